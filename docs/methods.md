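# Methods

## Model and assumptions

The package treats a signed directed protein network as a continuous
recurrent system. Edge signs (activation `+1`, inhibition `−1`) are fixed
biological knowledge; edge weight magnitudes in `(0, 1]` are the free
parameters. A drug is a set of clamped inputs (each target held at its
modulation sign throughout the run); disease semantics live entirely in
the effector signs `v_i`, not in the initial state, which is all-zero.
This separates "what the drug does to the network" (the propagation) from
"what the disease needs" (the reversal statistic), so the same trained
model scores any drug or target subset.

The transfer function is a damped saturating update
`s ← (1−λ)s + λ·tanh(Ws + b)` with synchronous updates. `tanh` keeps
every state in `[−1, 1]` and sign-interpretable; the damping makes cyclic
networks contract in practice. Whether the original modelling tradition
this follows clamps or merely initialises drug inputs is not observable
from outside; clamping was chosen because it makes target ablation
well-defined (removing a target removes its clamp, not a transient).

Runs that hit the iteration cap are returned with `converged=False` and
the last damped state rather than raising: a negative-feedback loop with
gain can oscillate indefinitely, and downstream scoring treats such
states as valid but logs them.

## Parameters that matter

| parameter | default | units / range | rationale |
|---|---|---|---|
| damping λ | 0.5 | (0, 1] | halves the update per step; contracts most cycles |
| tolerance τ | 1e−6 | state units | well below the sign dead-band |
| max iterations | 200 | — | ≫ network diameter at desk scales |
| sign dead-band ε | 1e−3 | state units | `\|y\| < ε` counts as "no signal"; shared by accuracy and intensity so training and scoring agree on what a sign is. The reversal formula divides by `\|y\|`, undefined at 0; "not reversed" is the conservative completion |
| annealing schedule | T0=1, γ=0.95, 50 steps/T, floor 1e−3 | — | desk-scale convergence on networks up to a few hundred nodes |
| proposal | ×exp(U(−0.5, 0.5)), clip to (0, 1] | — | multiplicative, sign-preserving |
| ensemble size N | caller-chosen | — | keep all solutions and report mean accuracy; an optional `min_accuracy` filter exists but is off by default, since the admission threshold for a "plausible" solution is a judgement call |
| MoA extraction | k_paths=3, min_support=0.5, ≤8 hops | — | simple paths only; length cap bounds enumeration |
| FDR threshold | 0.05 | — | standard step-up significance level |

Accuracy is the fraction of restrictions whose simulated sign matches the
required sign; it is undefined (an error) on an empty restriction set
rather than silently 0 or 1.

## Differential expression choices

The normality gate applies the Lilliefors test per cohort at α = 0.05 for
n > 4 (its table-based p-values extend above n = 20, so large groups are
gated the same way); groups of four or fewer observations route directly
to the Wilcoxon rank-sum test. The t-test is the Welch variant (unequal
variances are the safe default), two-sided. Direction comes from the
difference of group means of the values as given — the package assumes
the caller supplies appropriately (typically log-) transformed
intensities and imposes no fold-change threshold. Genes constant in both
cohorts are reported with p = 1 and a warning.

## Network proximity score

The secondary "association" readout between two protein sets is the mean,
over set A, of the shortest undirected path to the nearest member of
set B, ranked against `n_null` degree-preserving random relabelings
(nodes resampled within bins of width one in log2 degree; 1000 draws by
default). The score is the percentage of null draws at least as distant
as observed; unreachable pairs take diameter + 1. This is a
clearly-labelled distance percentile, not a claim to reproduce any
proprietary supervised score, and it is kept separate from the
mechanistic reversal statistic.

## Mechanism extraction conventions

Edge support is the share of solutions in which the edge, restricted to
edges with `|w|` above a small threshold (0.05), lies on a
target→effector path. Path ranking uses the product of edge supports,
with ties broken by shorter path then lexicographic node order, so
extraction is deterministic. After pruning at `min_support`, edges no
longer on any surviving target→effector path are dropped, which preserves
the invariant that everything retained is mechanistically connected.
Because edge signs are fixed network-wide, solutions cannot disagree on
an edge's sign, so no "ambiguous sign" tag is needed here.

## What the synthetic generator emulates — and what it does not

The generator produces the study conditions end to end: a
preferential-attachment signed network (defaults: 60 nodes, mean
out-degree 2.5, 30% inhibitory edges — sparse, hub-driven, with early
nodes as natural targets and late nodes as sinks); a planted true model
(weight magnitudes uniform in [0.3, 1] so planted signals clear the
dead-band over realistic path depths); an inhibitor drug with 3 targets;
10 effectors in 5 uniform-random motifs with pathological signs set so
the planted drug reverses exactly `round(ρ·n)` of them (ρ = 0.6 by
default); 30 restrictions equal to the true drug-on signs with a 5%
sign-flip rate; expression cohorts of 10 vs 10 with 500 genes, 10% truly
shifted by 2 SD; and paired bioflag panels of 20 patients with a planted
mean percent decline and lognormal assay noise (cv = 0.2 by default,
in the range of between-patient variability seen for circulating
inflammatory markers).

What it does not emulate: real interactome topology (no cliques, no
curated complexes), curated motif structure (motifs are random
partitions), correlated gene expression, batch effects, or assay
saturation at range limits. Passing tests therefore demonstrate that the
algorithms recover planted structure under their own generative
assumptions — not that any particular biological conclusion holds on real
data.

Target selection rejection-samples up to 20 target sets when a draw's
downstream signal cannot host the requested number of effectors (possible
for single-target scenarios on small networks); planting remains fully
deterministic given the seed.

## Numerical and degenerate-input conventions

- Duplicate edges with conflicting signs, duplicate profile entries and
  conflicting restrictions are hard errors; silent majority-voting would
  corrupt sign semantics.
- Restrictions naming proteins outside the network are dropped with a
  logged count (partial networks stay usable); absent drug targets or
  effectors are fatal validation findings.
- Delta changes round half-away-from-zero to integer percent and are
  computed on cohort means (the mean of per-patient percent changes is a
  secondary column); baseline ≤ 0 is a domain error.
- Annealing tracks the best-ever model, so the returned objective is
  monotone in the number of proposals; two runs with the same seed are
  bit-identical, and ensemble sub-seeds derive from the global seed via a
  seed sequence.
- Out-of-assay-range bioflag values are flagged, summarised anyway, and
  never silently dropped.

## Problem sizes used by the shipped tests and acceptance script

The default test scenario is the 60-node network above with 10-model
ensembles at the default annealing schedule for recovery checks, 3-model
ensembles at a shortened schedule (γ = 0.9, 20 steps per temperature,
floor 0.01) for the 20-seed target-ranking experiment, and 300-gene
cohorts across 10–20 seeds for null calibration. These sizes were chosen
as the smallest at which the planted effects are comfortably identifiable;
all of them are parameters, and larger studies only require passing larger
values.

## Known limitations

- Steady-state semantics: no kinetics, no time courses; oscillatory
  regimes are flagged, not resolved.
- One weight per edge, zero default biases: no context-specific edge
  strengths across cell types.
- Simulated annealing is the only sampler implemented; genetic-algorithm
  or gradient-based fitting would slot in behind the same `anneal`
  interface.
- The ensemble is an unweighted set of independent runs; no posterior
  weighting by accuracy is applied when averaging intensity.
- Accuracy against sign restrictions is a coarse objective: magnitudes
  carry no information beyond clearing the dead-band.
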