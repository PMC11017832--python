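"""Statistical machinery for the two study arms.

Thin, contract-checked wrappers around standard procedures (simple OLS,
one-way ANOVA, Pearson chi-square, grouped MAD outlier screening) plus the
study-specific summaries: per-stratum descriptive tables with exact pooled
weighted means, and the ±2 mm depth-prediction accuracy metric.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .index import cf_stratum

__all__ = [
    "RegressionResult",
    "StrataSummary",
    "ols_fit",
    "one_way_anova",
    "chi_square_prop",
    "prediction_accuracy",
    "mad_outlier_flags",
    "summarize_strata",
    "pooled_mean",
]

#: consistency scale factor making the MAD an estimate of a normal SD.
MAD_NORMAL_SCALE = 1.4826


@dataclass
class RegressionResult:
    """Simple linear regression y = intercept + slope*x."""

    slope: float
    intercept: float
    r2: float
    p_slope: float
    n: int
    se_slope: float

    def to_dict(self) -> dict:
        return asdict(self)

    def predict(self, x):
        return self.intercept + self.slope * np.asarray(x, dtype=float)


@dataclass
class StrataSummary:
    group_label: str
    n: int
    mean: float
    sd: float
    min: float
    max: float

    def to_dict(self) -> dict:
        return asdict(self)


def ols_fit(x: Sequence[float], y: Sequence[float]) -> RegressionResult:
    """Least-squares line with r², two-sided slope p (t on n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: x has {x.size}, y has {y.size}")
    if x.size < 3:
        raise ValueError(f"need at least 3 points, got {x.size}")
    if np.var(x) == 0:
        raise ValueError("degenerate design: x has zero variance")
    if np.var(y) == 0:  # flat response: zero slope, nothing explained
        return RegressionResult(
            slope=0.0, intercept=float(y[0]), r2=0.0, p_slope=1.0,
            n=int(x.size), se_slope=0.0,
        )
    fit = sps.linregress(x, y)
    return RegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r2=float(fit.rvalue**2),
        p_slope=float(fit.pvalue),
        n=int(x.size),
        se_slope=float(fit.stderr),
    )


def one_way_anova(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Classical one-way ANOVA F test across >= 2 groups of n >= 2."""
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError(f"need at least 2 groups, got {len(arrays)}")
    for i, g in enumerate(arrays):
        if g.size < 2:
            raise ValueError(f"group {i} has n={g.size} < 2")
    f, p = sps.f_oneway(*arrays)
    if np.isnan(f):  # all values identical in every group
        return 0.0, 1.0
    return float(f), float(p)


def chi_square_prop(table) -> tuple[float, float]:
    """Pearson chi-square on an r x k contingency table, no continuity correction."""
    tab = np.asarray(table, dtype=float)
    if tab.ndim != 2 or tab.shape[0] < 2 or tab.shape[1] < 2:
        raise ValueError(f"need an r x k table with r,k >= 2, got shape {tab.shape}")
    expected = sps.contingency.expected_freq(tab)
    if np.any(expected <= 0):
        raise ValueError(
            "zero expected count in the contingency table; an exact test would be "
            "required (out of scope)"
        )
    chi2, p, _, _ = sps.chi2_contingency(tab, correction=False)
    return float(chi2), float(p)


def prediction_accuracy(lesions, tolerance_mm: float = 2.0) -> tuple[float, int, int]:
    """Fraction of analyzable lesions with |depth - PFI/100| <= tolerance."""
    if tolerance_mm <= 0:
        raise ValueError(f"tolerance must be positive, got {tolerance_mm}")
    usable = [
        r for r in lesions
        if not r.excluded and r.attained_pfi is not None and r.depth_mm is not None
    ]
    if not usable:
        raise ValueError("no analyzable lesions with depth and attained PFI")
    hits = sum(
        1 for r in usable if abs(r.depth_mm - r.attained_pfi / 100.0) <= tolerance_mm
    )
    return hits / len(usable), hits, len(usable)


def mad_outlier_flags(
    values: Sequence[float],
    group_labels: Sequence,
    k: float = 3.0,
) -> np.ndarray:
    """Flag values deviating > k scaled-MADs from their group median.

    The deviation scale is the group median absolute deviation times
    1.4826 (normal-consistent).  Groups with fewer than 3 members are
    skipped with a warning and contribute no flags.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(group_labels)
    if values.shape != labels.shape:
        raise ValueError("values and group_labels must have equal length")
    flags = np.zeros(values.size, dtype=bool)
    for lab in np.unique(labels):
        idx = np.flatnonzero(labels == lab)
        if idx.size < 3:
            warnings.warn(
                f"group {lab!r} has n={idx.size} < 3; skipped in outlier screening",
                stacklevel=2,
            )
            continue
        g = values[idx]
        med = np.median(g)
        mad = sps.median_abs_deviation(g, scale="normal")
        flags[idx] = np.abs(g - med) > k * mad
    return flags


def pooled_mean(ns: Sequence[float], means: Sequence[float]) -> float:
    """Sample-size-weighted pooled mean: sum(n_i m_i) / sum(n_i)."""
    ns = np.asarray(ns, dtype=float)
    means = np.asarray(means, dtype=float)
    return float(np.dot(ns, means) / ns.sum())


_VARIABLES = {
    "depth": lambda r: r.depth_mm,
    "width": lambda r: r.width_mm,
    "pfi": lambda r: r.attained_pfi,
}

_GROUPINGS = {
    "dose": lambda r: r.n_applications,
    "cf_stratum": lambda r: cf_stratum(r.mean_cf_g),
    "pfi_stratum": lambda r: r.intended_pfi_target,
}


def summarize_strata(lesions, by: str, variable: str) -> list[StrataSummary]:
    """Per-stratum n/mean/SD/min/max plus a pooled row.

    ``by`` is one of dose / cf_stratum / pfi_stratum; ``variable`` one of
    depth / width / pfi.  Excluded lesions are dropped.  The pooled row's
    mean is the exact sample-size-weighted mean of the strata.
    """
    if by not in _GROUPINGS:
        raise ValueError(f"unknown grouping {by!r}; expected one of {sorted(_GROUPINGS)}")
    if variable not in _VARIABLES:
        raise ValueError(f"unknown variable {variable!r}; expected one of {sorted(_VARIABLES)}")
    get_group, get_val = _GROUPINGS[by], _VARIABLES[variable]
    usable = [r for r in lesions if not r.excluded and get_group(r) is not None]
    if not usable:
        raise ValueError("no analyzable lesions after exclusions")

    groups: dict = {}
    for r in usable:
        groups.setdefault(get_group(r), []).append(get_val(r))

    out = []
    for lab in sorted(groups, key=lambda v: (str(type(v)), v)):
        g = np.asarray(groups[lab], dtype=float)
        out.append(
            StrataSummary(
                group_label=str(lab),
                n=int(g.size),
                mean=float(g.mean()),
                sd=float(g.std(ddof=1)) if g.size > 1 else 0.0,
                min=float(g.min()),
                max=float(g.max()),
            )
        )
    allv = np.asarray([get_val(r) for r in usable], dtype=float)
    out.append(
        StrataSummary(
            group_label="pooled",
            n=int(allv.size),
            mean=pooled_mean([s.n for s in out], [s.mean for s in out]),
            sd=float(allv.std(ddof=1)) if allv.size > 1 else 0.0,
            min=float(allv.min()),
            max=float(allv.max()),
        )
    )
    return out
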