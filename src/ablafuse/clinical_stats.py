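"""Statistics over the clinical evaluation tables of the original 30-patient
/ 38-ablation series.

Two packaged CSV fixtures hold the published per-treatment data: per-lesion
tumor / ablation / residual volumes, and two radiologists' five-point scores
(registration quality, spatial position of the ablated area, clinical
indication, confidence improvement).  Registration quality was scored once
per treatment, so second-lesion rows leave those cells empty.  Transcription
is data entry; every aggregate here is recomputed from the rows.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .assessment import round_half_away

__all__ = [
    "ScoreTable",
    "ResidualTable",
    "load_score_table",
    "load_residual_table",
    "summarize_scores",
    "students_t",
    "residual_aggregates",
]

SCORE_CRITERIA = ["registration_quality", "position", "clinical_indication", "confidence"]
RATERS = ["r1", "r2"]


@dataclass
class ScoreTable:
    """Per-lesion five-point scores (1 poor ... 5 excellent), two raters per
    criterion."""

    rows: pd.DataFrame

    def __post_init__(self):
        for crit in SCORE_CRITERIA:
            for r in RATERS:
                col = f"{crit}_{r}"
                if col not in self.rows.columns:
                    raise ValueError(f"score table missing column {col}")
                vals = self.rows[col].dropna()
                if not vals.isin([1, 2, 3, 4, 5]).all():
                    raise ValueError(f"scores in {col} must be integers 1..5")

    def __len__(self):
        return len(self.rows)


@dataclass
class ResidualTable:
    """Per-lesion volumes (cm^3) and residual percentage of the initial
    tumor volume."""

    rows: pd.DataFrame

    def __post_init__(self):
        for col in ("tumor_volume_cm3", "ablation_volume_cm3",
                    "residual_volume_cm3", "residual_percentage"):
            if col not in self.rows.columns:
                raise ValueError(f"residual table missing column {col}")
            if (self.rows[col] < 0).any():
                raise ValueError(f"negative values in {col}")
        pct = self.rows["residual_percentage"]
        if (pct > 100).any():
            raise ValueError("residual percentage outside [0, 100]")

    def __len__(self):
        return len(self.rows)


def _packaged(name: str) -> pd.DataFrame:
    with resources.files("ablafuse.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def load_score_table(path=None) -> ScoreTable:
    """The packaged clinical-evaluation scores (or a user CSV with the same
    columns)."""
    return ScoreTable(pd.read_csv(path) if path is not None else _packaged("table2.csv"))


def load_residual_table(path=None) -> ResidualTable:
    return ResidualTable(pd.read_csv(path) if path is not None else _packaged("table1.csv"))


def summarize_scores(t: ScoreTable) -> dict:
    """Per-rater, per-criterion arithmetic mean and sample SD (n-1),
    reported to 1 decimal with the raw values retained."""
    if len(t) == 0:
        raise ValueError("empty score table")
    out = {}
    for crit in SCORE_CRITERIA:
        out[crit] = {}
        for r in RATERS:
            vals = t.rows[f"{crit}_{r}"].dropna().to_numpy(dtype=float)
            mean = float(vals.mean())
            sd = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
            out[crit][r] = {
                "n": int(vals.size),
                "mean": round_half_away(mean, 1),
                "sd": round_half_away(sd, 1),
                "mean_raw": mean,
                "sd_raw": sd,
            }
    return out


def students_t(a, b, mode: str = "unpaired_equal_var"):
    """Classic Student t statistic and two-sided p.

    ``unpaired_equal_var`` pools the variances; ``paired`` tests the
    differences.  Degenerate zero-variance inputs return the exact
    sentinels: t = 0, p = 1 when the means agree, else t = +/-inf, p = 0.
    """
    from scipy import stats

    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs n >= 2")
    if mode == "paired":
        if a.size != b.size:
            raise ValueError("paired mode requires equal-length samples")
        d = a - b
        if np.allclose(d.std(ddof=1), 0.0):
            if np.isclose(d.mean(), 0.0):
                return 0.0, 1.0
            return float(np.sign(d.mean()) * np.inf), 0.0
        res = stats.ttest_rel(a, b)
    elif mode == "unpaired_equal_var":
        pooled = ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1))
        if np.isclose(pooled, 0.0):
            if np.isclose(a.mean(), b.mean()):
                return 0.0, 1.0
            return float(np.sign(a.mean() - b.mean()) * np.inf), 0.0
        res = stats.ttest_ind(a, b, equal_var=True)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return float(res.statistic), float(res.pvalue)


def residual_aggregates(t: ResidualTable, retreat_threshold_pct: float = 20.0) -> dict:
    """Partition lesions into zero-residual / partial / missed and aggregate
    the partial percentages; ``n_retreat`` counts missed targets plus
    partials at/above the retreatment threshold."""
    if len(t) == 0:
        raise ValueError("empty residual table")
    pct = t.rows["residual_percentage"].to_numpy(dtype=float)
    zero = pct == 0
    missed = pct == 100
    partial = ~zero & ~missed
    p = pct[partial]
    n = pct.size
    out = {
        "n_total": int(n),
        "n_zero": int(zero.sum()),
        "n_partial": int(partial.sum()),
        "n_missed": int(missed.sum()),
        "partial_percentages": p.tolist(),
        "n_retreat": int(missed.sum() + (p >= retreat_threshold_pct).sum()),
        "partial_aggregates_defined": bool(partial.any()),
        "mean_pct": None,
        "sd_pct": None,
        "min_pct": None,
        "max_pct": None,
    }
    if partial.any():
        out["mean_pct"] = round_half_away(float(p.mean()), 1)
        out["sd_pct"] = round_half_away(float(p.std(ddof=1)), 1) if p.size > 1 else 0.0
        out["min_pct"] = float(p.min())
        out["max_pct"] = float(p.max())
    out["fractions"] = {
        "zero_pct": round_half_away(100.0 * out["n_zero"] / n, 1),
        "partial_pct": round_half_away(100.0 * out["n_partial"] / n, 1),
        "missed_pct": round_half_away(100.0 * out["n_missed"] / n, 1),
        "retreat_pct": round_half_away(100.0 * out["n_retreat"] / n, 1),
    }
    return out
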