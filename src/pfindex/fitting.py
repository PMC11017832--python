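"""Estimation of PF-index parameters from per-lesion data.

This is the characterization step: given measured (contact force, dose,
depth) triples, recover the index surface

    depth = (b0 + b1*F) * ln(n) + (c0 + c1*F) + noise

by least squares with the overall scale A fixed at 100 (the index is
reported on the PFI axis, depth on the mm axis; A is redundant with the
scale of b and c).  The surface is linear in (b0, b1, c0, c1), so the
unconstrained optimum is available in closed form; when it violates the
positivity of B(F) or C(F) on the supported force range, a constrained
multi-start refit takes over.

The module follows the statsmodels idiom: build a :class:`PFIndexModel`
from data, call :meth:`~PFIndexModel.fit`, inspect the returned
:class:`PFIndexResults` (estimates, standard errors, ``summary()``).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import LinearConstraint, minimize

from .index import FORCE_MAX_G, FORCE_MIN_G, IndexParameters

__all__ = ["PFIndexModel", "PFIndexResults", "FitResult", "fit_index_parameters", "DesignError"]


class DesignError(ValueError):
    """The lesion set cannot identify the index parameters."""


#: deterministic multi-start grid for the constrained refit.
_START_GRID = {
    "b0": (0.5, 1.5, 3.0),
    "c0": (0.5, 1.5, 3.0),
    "b1": (0.0, 0.02, 0.05),
    "c1": (0.0, 0.02, 0.05),
}

_PARAM_NAMES = ("b0", "b1", "c0", "c1")

#: relative rss-change convergence tolerance / rss tie tolerance.
_TOL = 1e-9


def _design_matrix(force: np.ndarray, logn: np.ndarray) -> np.ndarray:
    # columns ordered as (b0, b1, c0, c1)
    return np.column_stack([logn, force * logn, np.ones_like(force), force])


class PFIndexModel:
    """Least-squares model of lesion depth on the PF-index surface.

    Parameters
    ----------
    depth_mm, force_g, n_applications : array-like, one entry per lesion.
    a : fixed index scale (default 100; not estimated).
    excluded_ids : identifiers of records dropped before construction,
        carried through to the results for accounting.
    """

    def __init__(self, depth_mm, force_g, n_applications, a: float = 100.0,
                 excluded_ids: list | None = None):
        self.depth = np.asarray(depth_mm, dtype=float)
        self.force = np.asarray(force_g, dtype=float)
        self.doses = np.asarray(n_applications, dtype=float)
        if not (self.depth.shape == self.force.shape == self.doses.shape):
            raise ValueError("depth, force and dose arrays must have equal length")
        if np.any(self.doses < 1):
            raise ValueError("application counts must be >= 1")
        self.a = float(a)
        self.excluded_ids = list(excluded_ids or [])
        if np.unique(self.doses).size < 2:
            raise DesignError(
                "all lesions share a single dose level; the log-dose slope B(F) "
                "is unidentifiable — need >= 2 distinct application counts"
            )
        if np.unique(self.force).size < 2:
            raise DesignError(
                "all lesions share a single contact force; the force terms b1, c1 "
                "are unidentifiable — need >= 2 distinct forces"
            )
        self._X = _design_matrix(self.force, np.log(self.doses))

    # -- constructors -------------------------------------------------------

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, depth_col="depth_mm", force_col="mean_cf_g",
                       dose_col="n_applications", **kwargs) -> "PFIndexModel":
        return cls(df[depth_col], df[force_col], df[dose_col], **kwargs)

    @classmethod
    def from_lesions(cls, lesions, drop_excluded: bool = True) -> "PFIndexModel":
        """Build from LesionRecords, dropping excluded/transmural records."""
        kept, dropped = [], []
        for r in lesions:
            if drop_excluded and (r.excluded or r.transmural):
                dropped.append(r.lesion_id)
            else:
                kept.append(r)
        return cls(
            [r.depth_mm for r in kept],
            [r.mean_cf_g for r in kept],
            [r.n_applications for r in kept],
            excluded_ids=dropped,
        )

    # -- fitting ------------------------------------------------------------

    def _rss(self, theta: np.ndarray) -> float:
        resid = self.depth - self._X @ theta
        return float(resid @ resid)

    def _positivity_ok(self, theta: np.ndarray) -> bool:
        b0, b1, c0, c1 = theta
        return all(
            b0 + b1 * f > 0 and c0 + c1 * f > 0 for f in (FORCE_MIN_G, FORCE_MAX_G)
        )

    def fit(self) -> "PFIndexResults":
        """Fit by least squares; constrained multi-start when needed.

        The unconstrained closed-form solution is used when it already
        satisfies B(F) > 0 and C(F) > 0 on [5, 80] g (the generic case);
        otherwise the fit is repeated from a deterministic grid of starting
        values under those linear inequality constraints and the best
        (smallest-rss, then smallest-norm) solution is kept.
        """
        theta_free, _, rank, _ = np.linalg.lstsq(self._X, self.depth, rcond=None)
        if rank < 4:
            raise DesignError(
                "rank-deficient design: force and dose variation do not separate "
                "the four index parameters"
            )
        if self._positivity_ok(theta_free):
            theta, converged = theta_free, True
        else:
            theta, converged = self._fit_constrained()
        return self._make_results(theta, converged)

    def _fit_constrained(self) -> tuple[np.ndarray, bool]:
        # B and C are affine in F: positivity at both range endpoints suffices.
        con = LinearConstraint(
            np.array(
                [
                    [1.0, FORCE_MIN_G, 0.0, 0.0],
                    [1.0, FORCE_MAX_G, 0.0, 0.0],
                    [0.0, 0.0, 1.0, FORCE_MIN_G],
                    [0.0, 0.0, 1.0, FORCE_MAX_G],
                ]
            ),
            lb=1e-9,
        )
        best_theta, best_rss, best_ok = None, np.inf, False
        for b0, b1, c0, c1 in itertools.product(
            _START_GRID["b0"], _START_GRID["b1"], _START_GRID["c0"], _START_GRID["c1"]
        ):
            x0 = np.array([b0, b1, c0, c1])
            sol = minimize(
                lambda t: self._rss(t),
                x0,
                jac=lambda t: -2.0 * self._X.T @ (self.depth - self._X @ t),
                method="SLSQP",
                constraints=[{
                    "type": "ineq",
                    "fun": lambda t: con.A @ t - con.lb,
                    "jac": lambda t: con.A,
                }],
                options={"ftol": _TOL, "maxiter": 500},
            )
            rss = self._rss(sol.x)
            better = rss < best_rss * (1 - _TOL) - _TOL
            tie = best_theta is not None and abs(rss - best_rss) <= _TOL * max(best_rss, 1.0)
            if better or (tie and np.linalg.norm(sol.x) < np.linalg.norm(best_theta)):
                best_theta, best_rss, best_ok = sol.x, rss, bool(sol.success)
        return best_theta, best_ok

    def _make_results(self, theta: np.ndarray, converged: bool) -> "PFIndexResults":
        n, k = self.depth.size, 4
        rss = self._rss(theta)
        dof = max(n - k, 1)
        sigma2 = rss / dof
        xtx_inv = np.linalg.pinv(self._X.T @ self._X)
        bse = np.sqrt(np.clip(np.diag(xtx_inv) * sigma2, 0.0, None))
        try:
            params = IndexParameters(*theta, a=self.a)
        except ValueError:
            params = None
            converged = False
        return PFIndexResults(
            model=self,
            theta=theta,
            params=params,
            bse=bse,
            sigma_hat=math.sqrt(sigma2),
            rss=rss,
            n_used=n,
            df_resid=dof,
            converged=converged,
            excluded_ids=self.excluded_ids,
        )


@dataclass
class PFIndexResults:
    """Fitted PF-index surface with uncertainties and diagnostics."""

    model: PFIndexModel
    theta: np.ndarray
    params: IndexParameters | None
    bse: np.ndarray
    sigma_hat: float
    rss: float
    n_used: int
    df_resid: int
    converged: bool
    excluded_ids: list = field(default_factory=list)

    def predict_depth(self, force_g, n_applications) -> np.ndarray:
        """Expected depth (mm) at given force/dose under the fitted surface."""
        f = np.atleast_1d(np.asarray(force_g, dtype=float))
        n = np.atleast_1d(np.asarray(n_applications, dtype=float))
        X = _design_matrix(f, np.log(n))
        return X @ self.theta

    def predict_pfi(self, force_g, n_applications) -> np.ndarray:
        return self.model.a * self.predict_depth(force_g, n_applications)

    def to_dict(self) -> dict:
        return {
            "params": dict(zip(_PARAM_NAMES, map(float, self.theta))) | {"a": self.model.a},
            "bse": dict(zip(_PARAM_NAMES, map(float, self.bse))),
            "sigma_hat": self.sigma_hat,
            "rss": self.rss,
            "n_used": self.n_used,
            "converged": self.converged,
            "excluded_ids": list(self.excluded_ids),
        }

    def summary(self) -> str:
        lines = [
            "PF-index surface fit (A fixed at %.0f)" % self.model.a,
            f"  n_used = {self.n_used}   rss = {self.rss:.4f} mm^2   "
            f"sigma_hat = {self.sigma_hat:.3f} mm   converged = {self.converged}",
            "  param     estimate      std err",
        ]
        for name, est, se in zip(_PARAM_NAMES, self.theta, self.bse):
            lines.append(f"  {name:5s} {est:12.5f} {se:12.5f}")
        if self.excluded_ids:
            lines.append(f"  excluded records: {len(self.excluded_ids)}")
        return "\n".join(lines)


#: spec-facing alias: the characterization fit result object.
FitResult = PFIndexResults


def fit_index_parameters(lesions, fix_a: float = 100.0) -> PFIndexResults:
    """Fit the index surface to a lesion table (excluded records dropped)."""
    model = PFIndexModel.from_lesions(lesions)
    model.a = float(fix_a)
    return model.fit()
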