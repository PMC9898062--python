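"""Percentile-based exclusion of non-myofiber ROIs.

Automated laminin segmentation inevitably produces some non-fiber ROIs
(merged fibers, gaps, debris, longitudinally cut fibers).  Three filters
remove them, each with cuts computed over the FULL pooled ROI set so the
filters are order-independent:

1. segmentation certainty — percentile cuts on the classification-channel
   interior Mean and strip Mean_boundary (default 5th/95th);
2. cross-sectional area — percentile cuts on CSA (default 10th/99th),
   optionally per sample group when CSA distributions differ between
   groups;
3. circularity — ROIs above the pooled 1st percentile survive, rejecting
   elongated (longitudinally sectioned or merged) profiles.

Each ROI also gets an aggregate code in {0, 0.4, 0.7, 1} for overlay
rendering: 0 failed certainty, 0.4 survived only certainty, 0.7 survived
certainty+CSA, 1 survived everything.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import MFITable

AGGREGATE_CODES = (0.0, 0.4, 0.7, 1.0)


@dataclass
class CertaintyMetric:
    low_pct: float = 5.0
    high_pct: float = 95.0
    active: bool = True
    sided: str = "two"  # or "upper": only the high cut excludes

    def __post_init__(self) -> None:
        if self.active and not (0 <= self.low_pct < self.high_pct <= 100):
            raise ValueError("need 0 <= low < high <= 100")


@dataclass
class FilterConfig:
    """Thresholds of the three ROI filters.

    Defaults follow the published workflow; the percentiles are meant to
    be tuned per dataset by inspecting the metric density plots.
    """

    certainty_mean: CertaintyMetric = field(default_factory=CertaintyMetric)
    certainty_mean_boundary: CertaintyMetric = field(default_factory=CertaintyMetric)
    certainty_stddev_boundary: CertaintyMetric = field(
        default_factory=lambda: CertaintyMetric(active=False, sided="upper")
    )
    csa_low_pct: float = 10.0
    csa_high_pct: float = 99.0
    csa_group_by: str | None = None
    circularity_low_pct: float = 1.0
    min_fibers_per_sample: int = 100
    classification_channel: int = 5

    def __post_init__(self) -> None:
        if not (0 <= self.csa_low_pct < self.csa_high_pct <= 100):
            raise ValueError("CSA percentiles must satisfy 0 <= low < high <= 100")


def percentile_bounds(
    values: Sequence[float], low_pct: float, high_pct: float
) -> tuple[float, float]:
    """Linear-interpolation (rank type 7) percentile cut values."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("no values to take percentiles of")
    if v.size < 2:
        raise ValueError("need at least 2 values")
    lo, hi = np.percentile(v, [low_pct, high_pct])
    return float(lo), float(hi)


def _two_sided_pass(values: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Strictly-inside pass; the degenerate all-ties case excludes nothing."""
    if lo == hi:
        return np.ones(len(values), dtype=bool)
    return (values > lo) & (values < hi)


def _certainty_records(table: MFITable, channel: int) -> pd.DataFrame:
    df = table.to_dataframe()
    sub = df[df["channel"] == channel]
    if sub.empty:
        raise ValueError(f"no channel-{channel} (classification) records in table")
    return sub.set_index("roi_id")


def filter_certainty(table: MFITable, cfg: FilterConfig | None = None) -> pd.Series:
    """Per-ROI pass/fail on the classification-channel certainty metrics.

    Cuts are pooled percentiles over all ROIs; an ROI passes when every
    active metric lies strictly inside its cuts.
    """
    cfg = cfg or FilterConfig()
    sub = _certainty_records(table, cfg.classification_channel)
    metrics = {
        "Mean": cfg.certainty_mean,
        "Mean_boundary": cfg.certainty_mean_boundary,
        "StdDev_boundary": cfg.certainty_stddev_boundary,
    }
    ok = np.ones(len(sub), dtype=bool)
    for col, m in metrics.items():
        if not m.active:
            continue
        vals = sub[col].to_numpy(float)
        lo, hi = percentile_bounds(vals, m.low_pct, m.high_pct)
        if m.sided == "upper":
            ok &= vals < hi if lo != hi else np.ones(len(vals), bool)
        else:
            ok &= _two_sided_pass(vals, lo, hi)
    return pd.Series(ok, index=sub.index, name="pass_certainty")


def filter_csa(
    table: MFITable,
    cfg: FilterConfig | None = None,
    group_of: Mapping[str, str] | None = None,
) -> pd.Series:
    """Per-ROI pass/fail on cross-sectional area.

    Cuts are computed within each sample group (or one pooled group) over
    ALL ROIs — including those the certainty filter failed — so the
    filters stay order-independent.
    """
    cfg = cfg or FilterConfig()
    sub = _certainty_records(table, cfg.classification_channel)
    csa = sub["Area"]
    if group_of is None:
        groups = pd.Series("__all__", index=csa.index)
    else:
        missing = [r for r in csa.index if r not in group_of]
        if missing:
            raise ValueError(f"no group for ROI(s) {missing[:5]}")
        groups = pd.Series([group_of[r] for r in csa.index], index=csa.index)
    ok = pd.Series(False, index=csa.index, name="pass_csa")
    for g, vals in csa.groupby(groups):
        v = vals.to_numpy(float)
        if len(v) < 2:
            warnings.warn(
                f"group {g!r} has {len(v)} ROI(s); CSA filter passes it trivially",
                stacklevel=2,
            )
            ok.loc[vals.index] = True
            continue
        lo, hi = percentile_bounds(v, cfg.csa_low_pct, cfg.csa_high_pct)
        ok.loc[vals.index] = _two_sided_pass(v, lo, hi)
    return ok


def filter_circularity(
    table: MFITable, cfg: FilterConfig | None = None
) -> pd.Series:
    """Per-ROI pass/fail: circularity strictly above the pooled low cut."""
    cfg = cfg or FilterConfig()
    sub = _certainty_records(table, cfg.classification_channel)
    vals = sub["Circ."].to_numpy(float)
    if len(vals) < 2 or vals.min() == vals.max():
        ok = np.ones(len(vals), dtype=bool)
    else:
        cut = float(np.percentile(vals, cfg.circularity_low_pct))
        ok = vals > cut
        if not ok.any():  # degenerate ties at the cut
            ok = np.ones(len(vals), dtype=bool)
    return pd.Series(ok, index=sub.index, name="pass_circ")


def aggregate_codes(flags: pd.DataFrame) -> pd.Series:
    """Collapse the three pass flags into the overlay code.

    0 failed certainty; 0.4 passed certainty only; 0.7 passed certainty
    and CSA only; 1 passed all three.
    """
    for col in ("pass_certainty", "pass_csa", "pass_circ"):
        if col not in flags:
            raise ValueError(f"flags missing column {col}")
    code = np.zeros(len(flags))
    cert = flags["pass_certainty"].to_numpy(bool)
    csa = flags["pass_csa"].to_numpy(bool)
    circ = flags["pass_circ"].to_numpy(bool)
    code[cert] = 0.4
    code[cert & csa] = 0.7
    code[cert & csa & circ] = 1.0
    return pd.Series(code, index=flags.index, name="aggregate_code")


def apply_filters(
    table: MFITable,
    cfg: FilterConfig | None = None,
    group_of: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Run all three filters and the aggregate code; one row per ROI."""
    cfg = cfg or FilterConfig()
    flags = pd.concat(
        [
            filter_certainty(table, cfg),
            filter_csa(table, cfg, group_of),
            filter_circularity(table, cfg),
        ],
        axis=1,
    )
    flags["aggregate_code"] = aggregate_codes(flags)
    return flags


def select_replicate(
    surviving_counts: Mapping[object, int], min_fibers: int = 100
) -> object | None:
    """Pick the section with the most surviving fibers.

    Returns the winning section id, or None when even the best section
    has fewer than ``min_fibers`` surviving fibers (the sample is then
    excluded from downstream analysis).  Ties go to the lowest section id.
    """
    if not surviving_counts:
        raise ValueError("no sections to select from")
    best = min(
        surviving_counts,
        key=lambda s: (-surviving_counts[s], s),
    )
    if surviving_counts[best] < min_fibers:
        return None
    return best
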