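"""Participant filters, scoring rules, binarization, and descriptives.

Implements the screening-cohort preparation steps: exclusion of
insufficient-effort responders (mean response time per item below 2 s) and
of slow outliers (Tukey fence, Q3 + 1.5 x IQR), severity banding for the
nomophobia questionnaire (NMP-Q, mean item score) and for PHQ-9 / GAD-7
totals, the present/absent binarization used for Ising network estimation
(score > 0 means the symptom is present), comorbidity grouping at the
conventional > 9 caseness cutoffs, and per-item descriptive statistics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .models import BinaryMatrix, SymptomPanel

__all__ = [
    "FilterResult",
    "CohortSummary",
    "load_panel",
    "filter_by_response_time",
    "binarize",
    "classify_nomophobia",
    "classify_severity",
    "comorbidity_groups",
    "describe",
]

log = logging.getLogger(__name__)

FAST_CUTOFF_S = 2.0
CASENESS_CUTOFF = 9  # strict '>' on PHQ-9 and GAD-7 totals

SEVERITY_BANDS = {
    "PHQ": [(0, 4, "none or minimal"), (5, 9, "mild"), (10, 14, "moderate"),
            (15, 19, "moderately severe"), (20, 27, "severe")],
    "GAD": [(0, 4, "none or minimal"), (5, 9, "mild"), (10, 14, "moderate"),
            (15, 21, "severe")],
}


@dataclass
class FilterResult:
    """Outcome of the response-time screen; the three sets partition the input."""

    kept: np.ndarray
    fast: np.ndarray
    slow: np.ndarray
    slow_cutoff: float

    def __post_init__(self) -> None:
        n = len(self.kept) + len(self.fast) + len(self.slow)
        union = np.concatenate([self.kept, self.fast, self.slow])
        assert len(np.unique(union)) == n, "filter sets must partition the input"


@dataclass
class CohortSummary:
    """Table-style descriptives plus caseness group breakdown."""

    items: pd.DataFrame           # mean, sd, skewness, kurtosis, prevalence per item
    group_counts: dict[str, int]  # neither / depression_only / anxiety_only / both
    group_percentages: dict[str, float]
    severity_counts: dict[str, dict[str, int]]
    n: int

    def to_json_dict(self) -> dict:
        return {
            "n": self.n,
            "group_counts": self.group_counts,
            "group_percentages": self.group_percentages,
            "severity_counts": self.severity_counts,
        }


def load_panel(path: str | Path) -> SymptomPanel:
    """Read a participants x items CSV (PHQ1..PHQ9, GAD1..GAD7, optional
    NMP1..NMP16 and rt_per_item_s).

    Rows with any missing PHQ/GAD item are dropped with a logged count.
    """
    df = pd.read_csv(path)
    rt = None
    if "rt_per_item_s" in df.columns:
        rt = df.pop("rt_per_item_s")
    scales, ranges = {}, {}
    for col in df.columns:
        if col.startswith("PHQ"):
            scales[col], ranges[col] = "PHQ", (0, 3)
        elif col.startswith("GAD"):
            scales[col], ranges[col] = "GAD", (0, 3)
        elif col.startswith("NMP"):
            scales[col], ranges[col] = "NMP", (1, 7)
        else:
            raise ValueError(
                f"unrecognized column {col!r}: expected PHQ1..PHQ9, GAD1..GAD7, "
                "NMP1..NMP16 or rt_per_item_s"
            )
    core = [c for c in df.columns if scales[c] in ("PHQ", "GAD")]
    complete = df[core].notna().all(axis=1)
    n_dropped = int((~complete).sum())
    if n_dropped:
        log.info("dropped %d participants with missing PHQ/GAD items", n_dropped)
        df = df.loc[complete].reset_index(drop=True)
        if rt is not None:
            rt = rt.loc[complete].reset_index(drop=True)
    return SymptomPanel(
        scores=df.astype(int),
        item_scales=scales,
        score_ranges=ranges,
        response_times=rt,
    )


def filter_by_response_time(
    times: np.ndarray | pd.Series, order: str = "after"
) -> FilterResult:
    """Split participants into kept / too-fast / too-slow by mean item time.

    Fast responders are those with times strictly below 2 seconds.  Slow
    outliers exceed the Tukey fence Q3 + 1.5 x IQR (quartiles by linear
    interpolation).  With ``order="after"`` (default) the fence is computed
    on the sample remaining after fast removal; ``order="before"`` computes
    it on the full sample.
    """
    t = np.asarray(times, dtype=float)
    if t.size == 0:
        raise ValueError("empty response-time vector")
    if np.any(t <= 0):
        raise ValueError("response times must be positive")
    if order not in ("before", "after"):
        raise ValueError("order must be 'before' or 'after'")

    idx = np.arange(t.size)
    fast_mask = t < FAST_CUTOFF_S
    base = t[~fast_mask] if order == "after" else t
    if base.size == 0:
        raise ValueError("no participants remain after fast-responder removal")
    q1, q3 = np.percentile(base, [25, 75])
    cutoff = q3 + 1.5 * (q3 - q1)
    slow_mask = (~fast_mask) & (t > cutoff)
    kept_mask = ~fast_mask & ~slow_mask
    log.info(
        "response-time filter: %d fast (< %gs), %d slow (> %.3gs), %d kept",
        fast_mask.sum(), FAST_CUTOFF_S, slow_mask.sum(), cutoff, kept_mask.sum(),
    )
    return FilterResult(
        kept=idx[kept_mask], fast=idx[fast_mask], slow=idx[slow_mask],
        slow_cutoff=float(cutoff),
    )


def binarize(panel: SymptomPanel) -> BinaryMatrix:
    """Present/absent coding of the PHQ/GAD items: 1 iff score > 0."""
    items = [c for c in panel.items if panel.item_scales[c] in ("PHQ", "GAD")]
    if not items:
        raise ValueError("panel has no PHQ/GAD items to binarize")
    scores = panel.scores[items]
    if (scores.to_numpy() < 0).any():
        raise ValueError("negative scores cannot be binarized")
    data = (scores > 0).astype(np.int8)
    return BinaryMatrix(data, panel.communities())


def classify_nomophobia(panel: SymptomPanel) -> pd.DataFrame:
    """NMP-Q severity from the mean item score.

    Bands: none (mean = 1), mild (1 < mean < 3), moderate (3 <= mean < 5),
    severe (mean >= 5).  The inclusion flag marks at least mild nomophobia
    (mean strictly above 1).
    """
    nmp_items = panel.items_of("NMP")
    if not nmp_items:
        raise ValueError("panel has no NMP items")
    mean = panel.scores[nmp_items].mean(axis=1)
    band = pd.cut(
        mean,
        bins=[-np.inf, 1.0, 3.0, 5.0, np.inf],
        labels=["none", "mild", "moderate", "severe"],
        right=False,
    ).astype(str)
    band[mean == 1.0] = "none"  # right-open bins put the boundary 1.0 in 'mild'
    return pd.DataFrame({"mean_score": mean, "band": band, "included": mean > 1.0})


def classify_severity(total: int, scale: str) -> str:
    """Severity band for a PHQ-9 (0-27) or GAD-7 (0-21) total score."""
    if scale not in SEVERITY_BANDS:
        raise ValueError("scale must be 'PHQ' or 'GAD'")
    bands = SEVERITY_BANDS[scale]
    if not (bands[0][0] <= total <= bands[-1][1]):
        raise ValueError(f"{scale} total {total} outside [{bands[0][0]}, {bands[-1][1]}]")
    for lo, hi, name in bands:
        if lo <= total <= hi:
            return name
    raise AssertionError("unreachable: bands cover the full range")


def comorbidity_groups(
    phq_totals: np.ndarray | pd.Series, gad_totals: np.ndarray | pd.Series
) -> tuple[dict[str, int], dict[str, float]]:
    """Caseness breakdown at strict > 9 cutoffs on both totals.

    Returns counts and percentages (one decimal) for the four mutually
    exclusive groups: neither, depression_only, anxiety_only, both.
    """
    phq = np.asarray(phq_totals)
    gad = np.asarray(gad_totals)
    if phq.shape != gad.shape:
        raise ValueError("PHQ and GAD totals must be aligned by participant")
    dep = phq > CASENESS_CUTOFF
    anx = gad > CASENESS_CUTOFF
    n = phq.size
    counts = {
        "neither": int(np.sum(~dep & ~anx)),
        "depression_only": int(np.sum(dep & ~anx)),
        "anxiety_only": int(np.sum(~dep & anx)),
        "both": int(np.sum(dep & anx)),
    }
    percentages = {k: round(100.0 * v / n, 1) for k, v in counts.items()}
    return counts, percentages


def describe(panel: SymptomPanel) -> CohortSummary:
    """Per-item descriptives plus caseness and severity breakdowns.

    SD uses the n-1 denominator; skewness and kurtosis are the
    bias-corrected sample versions (kurtosis is excess kurtosis, normal =
    0).  Constant items get NaN skewness/kurtosis.  Prevalence is the
    fraction of nonzero scores.
    """
    if panel.n == 0:
        raise ValueError("empty panel")
    rows = []
    for item in panel.items:
        x = panel.scores[item].to_numpy(dtype=float)
        sd = float(np.std(x, ddof=1)) if len(x) > 1 else 0.0
        if sd == 0:
            skew = kurt = np.nan
        else:
            skew = float(stats.skew(x, bias=False))
            kurt = float(stats.kurtosis(x, bias=False))
        rows.append({
            "item": item,
            "scale": panel.item_scales[item],
            "mean": float(np.mean(x)),
            "sd": sd,
            "skewness": skew,
            "kurtosis": kurt,
            "prevalence": float(np.mean(x > 0)),
        })
    items_df = pd.DataFrame(rows).set_index("item")

    phq_tot = panel.total("PHQ")
    gad_tot = panel.total("GAD")
    counts, percentages = comorbidity_groups(phq_tot, gad_tot)
    severity = {
        "PHQ": pd.Series([classify_severity(t, "PHQ") for t in phq_tot])
        .value_counts().to_dict(),
        "GAD": pd.Series([classify_severity(t, "GAD") for t in gad_tot])
        .value_counts().to_dict(),
    }
    return CohortSummary(
        items=items_df,
        group_counts=counts,
        group_percentages=percentages,
        severity_counts=severity,
        n=panel.n,
    )
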