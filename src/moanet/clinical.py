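"""Cohort summaries and delta changes of circulating bioflags.

A bioflag panel records paired concentrations (baseline and follow-up)
for each patient and analyte, together with per-analyte assay metadata
(range, units, sensitivity).  The headline readout is the *delta change*:
the percent change of the cohort-mean concentration between baseline and
follow-up, rounded half-away-from-zero to an integer percent.  Note this
is the change of means, not the mean of per-patient changes; the latter
is reported as a secondary column.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from .core import ConfigError, SchemaError

logger = logging.getLogger(__name__)

__all__ = [
    "AnalyteSpec",
    "BioflagPanel",
    "delta_change",
    "summarize_panel",
    "range_check",
    "load_panel",
]

BASELINE = "baseline"
FOLLOWUP = "month12"


@dataclass(frozen=True)
class AnalyteSpec:
    """Assay metadata for one analyte."""

    name: str
    range_min: float
    range_max: float
    units: str = "pg/mL"
    sensitivity: float | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.range_min < self.range_max):
            raise ConfigError(
                f"invalid assay range ({self.range_min}, {self.range_max}) for {self.name}"
            )


@dataclass(frozen=True)
class BioflagPanel:
    """Long-format paired measurements plus per-analyte assay metadata.

    ``data`` columns: patient_id, analyte, timepoint (baseline | month12),
    concentration.  Concentrations must be non-negative; values outside an
    analyte's assay range are flagged, never dropped.
    """

    data: pd.DataFrame
    analytes: Mapping[str, AnalyteSpec] = field(default_factory=dict)
    followup_label: str = FOLLOWUP

    def __post_init__(self) -> None:
        required = {"patient_id", "analyte", "timepoint", "concentration"}
        missing = required - set(self.data.columns)
        if missing:
            raise SchemaError(f"panel data missing column(s): {sorted(missing)}")
        if (self.data["concentration"] < 0).any():
            raise SchemaError("negative concentration in panel data")
        bad = set(self.data["timepoint"]) - {BASELINE, self.followup_label}
        if bad:
            raise SchemaError(f"unknown timepoint label(s): {sorted(bad)}")


def delta_change(baseline_mean: float, followup_mean: float) -> int:
    """Percent change of a cohort mean, rounded half-away-from-zero.

    ``round(100 * (followup - baseline) / baseline)``; e.g. a mean falling
    from 290 to 249 pg/mL is a delta change of -14%.
    """
    if baseline_mean <= 0:
        raise ValueError(f"baseline mean must be positive, got {baseline_mean}")
    pct = 100.0 * (followup_mean - baseline_mean) / baseline_mean
    return int(math.copysign(math.floor(abs(pct) + 0.5), pct))


def summarize_panel(panel: BioflagPanel) -> pd.DataFrame:
    """Per-analyte mean, SD, SEM and n per timepoint, plus delta changes.

    Only patients with both timepoints contribute to an analyte's summary
    (pairwise-complete); the number excluded is logged.  Analytes with no
    complete pair are excluded with a warning.  Columns ``delta_percent``
    (change of means) and ``mean_patient_delta_percent`` (mean of
    per-patient percent changes, unrounded) are both reported.
    """
    rows = []
    wide = panel.data.pivot_table(
        index=["analyte", "patient_id"],
        columns="timepoint",
        values="concentration",
        aggfunc="first",
    )
    for analyte in sorted(panel.data["analyte"].unique()):
        sub = wide.loc[analyte]
        for tp in (BASELINE, panel.followup_label):
            if tp not in sub.columns:
                sub[tp] = float("nan")
        complete = sub.dropna(subset=[BASELINE, panel.followup_label])
        n_excluded = len(sub) - len(complete)
        if n_excluded:
            logger.info(
                "%s: excluded %d patient(s) missing a timepoint", analyte, n_excluded
            )
        if complete.empty:
            logger.warning("%s: no patient with both timepoints; excluded", analyte)
            continue
        base = complete[BASELINE]
        post = complete[panel.followup_label]
        n = len(complete)
        rows.append(
            {
                "analyte": analyte,
                "n": n,
                "baseline_mean": base.mean(),
                "baseline_sd": base.std(ddof=1) if n > 1 else 0.0,
                "baseline_sem": (base.std(ddof=1) / math.sqrt(n)) if n > 1 else 0.0,
                "followup_mean": post.mean(),
                "followup_sd": post.std(ddof=1) if n > 1 else 0.0,
                "followup_sem": (post.std(ddof=1) / math.sqrt(n)) if n > 1 else 0.0,
                "delta_percent": delta_change(base.mean(), post.mean()),
                "mean_patient_delta_percent": float(
                    (100.0 * (post - base) / base).mean()
                ),
            }
        )
    return pd.DataFrame(rows).set_index("analyte") if rows else pd.DataFrame()


def range_check(panel: BioflagPanel) -> pd.DataFrame:
    """Flag each measurement against its analyte's declared assay range.

    Returns the panel rows with an added ``flag`` column taking values
    ``below-range``, ``in-range`` or ``above-range``.  Analytes without
    range metadata are a configuration error.
    """
    missing = set(panel.data["analyte"]) - set(panel.analytes)
    if missing:
        raise ConfigError(f"no assay range metadata for analyte(s): {sorted(missing)}")
    out = panel.data.copy()

    def flag(row: pd.Series) -> str:
        spec = panel.analytes[row["analyte"]]
        c = row["concentration"]
        if c < spec.range_min:
            return "below-range"
        if c > spec.range_max:
            return "above-range"
        return "in-range"

    out["flag"] = out.apply(flag, axis=1)
    return out


def load_panel(data_path: str | Path, metadata_path: str | Path | None = None) -> BioflagPanel:
    """Read a long-format panel CSV and optional YAML assay metadata.

    Metadata YAML maps analyte name to ``{range: [min, max], units,
    sensitivity}``.
    """
    data = pd.read_csv(data_path)
    analytes: dict[str, AnalyteSpec] = {}
    if metadata_path is not None:
        meta = yaml.safe_load(Path(metadata_path).read_text()) or {}
        for name, m in meta.items():
            analytes[name] = AnalyteSpec(
                name=name,
                range_min=float(m["range"][0]),
                range_max=float(m["range"][1]),
                units=m.get("units", "pg/mL"),
                sensitivity=m.get("sensitivity"),
            )
    return BioflagPanel(data=data, analytes=analytes)
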