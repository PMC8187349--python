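"""Two-cohort differential expression and restriction derivation.

Per gene, the test is chosen by a normality gate: when both cohorts pass
the Lilliefors test (applied for n > 4; groups of four or fewer fall back
to the rank test) a Welch two-sample t-test is used, otherwise the
Wilcoxon rank-sum test.  P-values are corrected across genes with the
Benjamini–Hochberg step-up procedure and genes at FDR < 0.05 become
signed restrictions: +1 when the case mean exceeds the control mean,
-1 otherwise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.diagnostic import lilliefors
from statsmodels.stats.multitest import multipletests

from .core import ConflictError, InsufficientSampleError, RestrictionSet, SchemaError

logger = logging.getLogger(__name__)

__all__ = [
    "DexResult",
    "normality_gate",
    "diff_expression",
    "restrictions_from_dex",
    "FDR_THRESHOLD",
    "LILLIEFORS_ALPHA",
]

FDR_THRESHOLD = 0.05
LILLIEFORS_ALPHA = 0.05


@dataclass(frozen=True)
class DexResult:
    """Per-gene differential-expression calls.

    ``table`` is indexed by gene with columns ``test`` ("t" | "wilcoxon"),
    ``pvalue``, ``fdr``, ``direction`` (+1 case > control mean, -1
    otherwise) and ``significant`` (FDR < 0.05).
    """

    table: pd.DataFrame
    fdr_threshold: float = FDR_THRESHOLD

    @property
    def significant_genes(self) -> pd.Index:
        return self.table.index[self.table["significant"]]

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index_label="gene")


def _passes_lilliefors(values: np.ndarray, alpha: float) -> bool:
    if np.ptp(values) == 0:  # degenerate: zero variance, cannot be Gaussian
        return False
    _, pval = lilliefors(values, dist="norm", pvalmethod="table")
    return bool(pval > alpha)


def normality_gate(
    values_a: np.ndarray, values_b: np.ndarray, alpha: float = LILLIEFORS_ALPHA
) -> str:
    """Choose ``"t"`` when both samples look Gaussian, else ``"wilcoxon"``.

    The Lilliefors composite-normality test is applied to each group at
    ``alpha``; it requires more than four observations, so groups with
    n <= 4 route to the rank test.  Fewer than two observations in either
    group is an error.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InsufficientSampleError(
            f"need n >= 2 in both groups, got {a.size} and {b.size}"
        )
    if a.size <= 4 or b.size <= 4:
        return "wilcoxon"
    if _passes_lilliefors(a, alpha) and _passes_lilliefors(b, alpha):
        return "t"
    return "wilcoxon"


def _gene_test(case: np.ndarray, control: np.ndarray) -> tuple[str, float]:
    if np.ptp(case) == 0 and np.ptp(control) == 0:
        return "constant", 1.0
    test = normality_gate(case, control)
    if test == "t":
        stat = stats.ttest_ind(case, control, equal_var=False)
    else:
        stat = stats.ranksums(case, control)
    p = float(stat.pvalue)
    return test, 1.0 if np.isnan(p) else p


def diff_expression(
    case_matrix: pd.DataFrame, control_matrix: pd.DataFrame
) -> DexResult:
    """Per-gene two-cohort tests with BH correction across all genes.

    Both matrices are genes x samples with matching gene indices (order
    may differ).  Genes constant in both cohorts are reported with p = 1
    and a warning.  Values are tested as given (log transformation, if
    appropriate, is the caller's responsibility).
    """
    if case_matrix.index.duplicated().any() or control_matrix.index.duplicated().any():
        raise ConflictError("duplicate gene rows in expression matrix")
    if set(case_matrix.index) != set(control_matrix.index):
        raise SchemaError("case and control matrices have different gene rows")
    control_matrix = control_matrix.loc[case_matrix.index]

    records = []
    n_constant = 0
    for gene in case_matrix.index:
        case = case_matrix.loc[gene].to_numpy(dtype=float)
        control = control_matrix.loc[gene].to_numpy(dtype=float)
        test, p = _gene_test(case, control)
        if test == "constant":
            n_constant += 1
            test = "t"
        direction = 1 if case.mean() > control.mean() else -1
        records.append((gene, test, p, direction))
    if n_constant:
        logger.warning("%d gene(s) constant in both cohorts; reported with p = 1", n_constant)

    table = pd.DataFrame.from_records(
        records, columns=["gene", "test", "pvalue", "direction"]
    ).set_index("gene")
    table["fdr"] = multipletests(table["pvalue"], method="fdr_bh")[1]
    table["significant"] = table["fdr"] < FDR_THRESHOLD
    return DexResult(table=table)


def restrictions_from_dex(dex: DexResult) -> RestrictionSet:
    """Significant genes become signed restrictions (provenance tagged)."""
    sig = dex.table[dex.table["significant"]]
    if sig.empty:
        logger.warning("no significant genes; restriction set is empty")
    entries = tuple(
        (gene, int(row["direction"])) for gene, row in sig.iterrows()
    )
    return RestrictionSet(entries=entries, provenance="derived-from-expression")
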