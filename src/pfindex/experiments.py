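"""Replicate (Monte-Carlo) experiments over the synthetic generators.

Each experiment regenerates many independent synthetic datasets under the
study conditions, applies the corresponding analysis, and returns
replicate-averaged statistics with their Monte-Carlo standard errors.
These are the quantities compared against the published values.
"""

from __future__ import annotations

import numpy as np

from .datagen import (
    default_char_config,
    default_validation_config,
    generate_characterization_lesions,
    generate_validation_lesions,
)
from .fitting import PFIndexModel
from .index import IndexParameters
from .stats import ols_fit, prediction_accuracy

__all__ = [
    "replicate_seeds",
    "validation_regression_experiment",
    "validation_accuracy_experiment",
    "characterization_experiment",
    "recovery_experiment",
]


def replicate_seeds(seed: int, n_reps: int) -> list[int]:
    """Independent per-replicate seeds derived from one base seed (< 2^31)."""
    state = np.random.SeedSequence(int(seed)).generate_state(n_reps, dtype=np.uint32)
    return [int(s & 0x7FFFFFFF) for s in state]


def _mean_se(values) -> dict:
    a = np.asarray(values, dtype=float)
    return {"mean": float(a.mean()), "mc_se": float(a.std(ddof=1) / np.sqrt(a.size))}


def validation_regression_experiment(seed: int, n_reps: int = 500, mode: str = "A_linear") -> dict:
    """Replicate-averaged OLS of depth on PFI/100 over validation datasets.

    Also tracks the mean depth within the 300-target stratum, a cross-check
    that the regression-calibrated generator reproduces the published
    stratum summary it was *not* calibrated to.
    """
    slopes, intercepts, r2s, depth300 = [], [], [], []
    for s in replicate_seeds(seed, n_reps):
        lesions = generate_validation_lesions(default_validation_config(mode, s))
        x = np.array([r.attained_pfi for r in lesions]) / 100.0
        y = np.array([r.depth_mm for r in lesions])
        reg = ols_fit(x, y)
        slopes.append(reg.slope)
        intercepts.append(reg.intercept)
        r2s.append(reg.r2)
        in300 = [r.depth_mm for r in lesions if r.intended_pfi_target == 300]
        depth300.append(float(np.mean(in300)))
    return {
        "n_reps": n_reps,
        "n_lesions": 73,
        "slope": _mean_se(slopes),
        "intercept": _mean_se(intercepts),
        "r2": _mean_se(r2s),
        "depth_mean_300_stratum": _mean_se(depth300),
    }


def validation_accuracy_experiment(seed: int, n_reps: int = 1000, mode: str = "B_strata",
                                   tolerance_mm: float = 2.0) -> dict:
    """Replicate-averaged ±tolerance depth-prediction accuracy (fraction)."""
    fracs = []
    for s in replicate_seeds(seed, n_reps):
        lesions = generate_validation_lesions(default_validation_config(mode, s))
        frac, _, _ = prediction_accuracy(lesions, tolerance_mm)
        fracs.append(frac)
    return {"n_reps": n_reps, "n_lesions": 73, "accuracy": _mean_se(fracs)}


def characterization_experiment(seed: int, n_reps: int = 500, n_lesions: int = 111) -> dict:
    """Replicate-averaged characterization marginals under the calibrated generator.

    Per replicate: mean depth at the x3 and x12 dose levels, the CF-only
    depth regression (slope, r²), and the overall depth and width means.
    """
    m3, m12, slopes, r2s, dmeans, wmeans = [], [], [], [], [], []
    for s in replicate_seeds(seed, n_reps):
        lesions = generate_characterization_lesions(default_char_config(s, n_lesions))
        kept = [r for r in lesions if not r.excluded]
        depth = np.array([r.depth_mm for r in kept])
        width = np.array([r.width_mm for r in kept])
        force = np.array([r.mean_cf_g for r in kept])
        doses = np.array([r.n_applications for r in kept])
        m3.append(float(depth[doses == 3].mean()))
        m12.append(float(depth[doses == 12].mean()))
        reg = ols_fit(force, depth)
        slopes.append(reg.slope)
        r2s.append(reg.r2)
        dmeans.append(float(depth.mean()))
        wmeans.append(float(width.mean()))
    return {
        "n_reps": n_reps,
        "n_lesions": n_lesions,
        "depth_mean_x3": _mean_se(m3),
        "depth_mean_x12": _mean_se(m12),
        "cf_slope": _mean_se(slopes),
        "cf_r2": _mean_se(r2s),
        "depth_mean_overall": _mean_se(dmeans),
        "width_mean_overall": _mean_se(wmeans),
    }


#: recovery-benchmark design: a single-application arm is included because
#: the offset C(F) cannot be pinned to 10% at sigma=0.3 without
#: near-zero log-dose leverage.
RECOVERY_DOSES = (1, 3, 6, 12)
RECOVERY_TRUTH = IndexParameters(b0=1.5, b1=0.03, c0=2.0, c1=0.04)


def recovery_experiment(seed: int, n_reps: int = 100, n_lesions: int = 500,
                        sigma: float = 0.3,
                        truth: IndexParameters = RECOVERY_TRUTH) -> dict:
    """Parameter-recovery benchmark for the index fit.

    Generates ``n_reps`` datasets from known parameters (forces uniform on
    5-80 g, doses cycling over the benchmark levels), refits, and reports
    the fraction of replicates in which each parameter lands within 10% of
    its true value.
    """
    names = ("b0", "b1", "c0", "c1")
    true_vec = np.array([truth.b0, truth.b1, truth.c0, truth.c1])
    within = np.zeros((n_reps, 4), dtype=bool)
    for i, s in enumerate(replicate_seeds(seed, n_reps)):
        rng = np.random.default_rng(s)
        force = rng.uniform(5.0, 80.0, n_lesions)
        doses = np.tile(RECOVERY_DOSES, n_lesions // len(RECOVERY_DOSES) + 1)[:n_lesions]
        depth = (
            (truth.b0 + truth.b1 * force) * np.log(doses)
            + (truth.c0 + truth.c1 * force)
            + rng.normal(0.0, sigma, n_lesions)
        )
        res = PFIndexModel(depth, force, doses).fit()
        within[i] = np.abs(res.theta - true_vec) <= 0.10 * np.abs(true_vec)
    return {
        "n_reps": n_reps,
        "n_lesions": n_lesions,
        "sigma": sigma,
        "fraction_within_10pct": {
            name: float(within[:, j].mean()) for j, name in enumerate(names)
        },
    }
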