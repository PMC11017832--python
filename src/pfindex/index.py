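"""Core PF-index computations.

The PF index is a lesion-quality score for pulsed field ablation (PFA)
combining the catheter contact force (CF, grams) and the number of PFA
applications delivered ("dose") into a single number whose value divided
by 100 predicts the ventricular lesion depth in millimetres:

    PFI(F, n) = A * (B(F) * ln(n) + C(F))

with ``B(F) = b0 + b1*F`` (the dose log-slope, mm) and ``C(F) = c0 + c1*F``
(the single-application offset, mm) affine in force, and ``A`` fixed at 100
so that B and C are expressed directly in millimetres of expected depth.

The logarithmic dose term encodes the asymptotically increasing
depth-vs-dose relationship observed in swine ventricles: successive
applications deepen the lesion by strictly diminishing increments.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from typing import Sequence

__all__ = [
    "IndexParameters",
    "AblationRun",
    "ForceRangeError",
    "pf_index",
    "expected_depth",
    "simulate_titration",
    "cf_stratum",
    "pfi_stratum",
    "CF_STRATA_BOUNDS",
    "PFI_TARGETS",
    "FORCE_MIN_G",
    "FORCE_MAX_G",
]

#: supported contact-force range (g); ablations were never performed below
#: 5 g and data above 80 g are excluded from analyses.
FORCE_MIN_G = 5.0
FORCE_MAX_G = 80.0

#: CF strata used throughout: low 5-25 g, high 26-50 g, very high 51-80 g.
#: Stored as right-closed interval upper edges.
CF_STRATA_BOUNDS = {"low": (5.0, 25.0), "high": (25.0, 50.0), "very_high": (50.0, 80.0)}

#: protocol titration targets for the validation study.
PFI_TARGETS = (300, 450, 600)


class ForceRangeError(ValueError):
    """Contact force outside the supported ablation range."""


@dataclass(frozen=True)
class IndexParameters:
    """Constants of the PF-index formula and its force dependence.

    Parameters
    ----------
    a : dimensionless overall scale, fixed at 100 by convention so that
        ``pf_index / 100`` is the expected lesion depth in mm.
    b0 : mm, force-independent part of the dose log-slope B(F).
    b1 : mm per gram, force sensitivity of the log-slope.
    c0 : mm, force-independent part of the offset C(F).
    c1 : mm per gram, force sensitivity of the offset.

    Validity requires the index to be strictly positive and strictly
    increasing in application count over the supported force range, i.e.
    A > 0, B(F) > 0 and C(F) > 0 for all F in [5, 80] g.  B and C are
    affine, so positivity at the two endpoints suffices.
    """

    b0: float
    b1: float
    c0: float
    c1: float
    a: float = 100.0

    def __post_init__(self) -> None:
        if not self.a > 0:
            raise ValueError(f"scale constant A must be positive, got {self.a}")
        for lo_hi in (FORCE_MIN_G, FORCE_MAX_G):
            if not self.log_slope(lo_hi) > 0:
                raise ValueError(
                    f"B(F)=b0+b1*F must be positive on [{FORCE_MIN_G}, {FORCE_MAX_G}] g; "
                    f"B({lo_hi}) = {self.log_slope(lo_hi):.4g}"
                )
            if not self.offset(lo_hi) > 0:
                raise ValueError(
                    f"C(F)=c0+c1*F must be positive on [{FORCE_MIN_G}, {FORCE_MAX_G}] g; "
                    f"C({lo_hi}) = {self.offset(lo_hi):.4g}"
                )

    def log_slope(self, force_g: float) -> float:
        """B(F) = b0 + b1*F, the per-ln(n) depth gain at force F (mm)."""
        return self.b0 + self.b1 * force_g

    def offset(self, force_g: float) -> float:
        """C(F) = c0 + c1*F, the single-application expected depth (mm)."""
        return self.c0 + self.c1 * force_g

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "IndexParameters":
        return cls(**{k: float(v) for k, v in d.items()})


def pf_index(force_g: float, n_applications: int, params: IndexParameters) -> float:
    """Evaluate the PF index at a mean contact force and application count.

    Parameters
    ----------
    force_g : mean contact force over the delivered applications, grams;
        must lie in the supported [5, 80] g range.
    n_applications : number of PFA applications (dose), >= 1.
    params : calibrated :class:`IndexParameters`.

    Returns
    -------
    float
        ``A * (B(F) * ln(n) + C(F))``; strictly positive.
    """
    f = float(force_g)
    if not math.isfinite(f):
        raise ForceRangeError(f"contact force must be finite, got {force_g}")
    if f < FORCE_MIN_G:
        raise ForceRangeError(
            f"contact force {f:g} g below the supported CF bound of {FORCE_MIN_G:g} g"
        )
    if f > FORCE_MAX_G:
        raise ForceRangeError(
            f"contact force {f:g} g above the supported CF bound of {FORCE_MAX_G:g} g"
        )
    n = int(n_applications)
    if n != n_applications or n < 1:
        raise ValueError(f"n_applications must be a positive integer, got {n_applications}")
    return params.a * (params.log_slope(f) * math.log(n) + params.offset(f))


def expected_depth(pfi: float) -> float:
    """Expected lesion depth (mm) for an attained PF index: PFI / 100."""
    if pfi < 0:
        raise ValueError(f"PF index must be non-negative, got {pfi}")
    return float(pfi) / 100.0


@dataclass
class AblationRun:
    """One titration-to-target delivery session.

    Applications are delivered one at a time; after each, the cumulative
    index is re-evaluated at the running-mean force.  Delivery stops at the
    first application where the index reaches the target ("foot pedal"), or
    at the application cap.
    """

    target_pfi: float
    force_trace: list[float]
    applications_delivered: int
    pfi_trajectory: list[float]
    attained_pfi: float
    stopped_reason: str  # "target_reached" | "max_applications"

    def to_json(self, **kwargs) -> str:
        return json.dumps(asdict(self), **kwargs)

    @classmethod
    def from_json(cls, s: str) -> "AblationRun":
        return cls(**json.loads(s))


def simulate_titration(
    target_pfi: float,
    force_trace: Sequence[float],
    params: IndexParameters,
    max_applications: int = 14,
) -> AblationRun:
    """Deliver PFA applications until the running PF index reaches a target.

    After application k the cumulative index is
    ``pf_index(mean(force_trace[:k]), k)`` — force is summarized as the
    running mean of per-application forces, matching the single mean CF
    reported per lesion.  ``force_trace`` is recycled if shorter than
    ``max_applications``.

    Returns the full :class:`AblationRun` including the trajectory.
    """
    if target_pfi <= 0:
        raise ValueError(f"target PF index must be positive, got {target_pfi}")
    if max_applications < 1:
        raise ValueError(f"max_applications must be >= 1, got {max_applications}")
    forces = [float(f) for f in force_trace]
    if not forces:
        raise ValueError("force_trace must be non-empty")

    delivered: list[float] = []
    trajectory: list[float] = []
    stopped = "max_applications"
    for k in range(1, max_applications + 1):
        delivered.append(forces[(k - 1) % len(forces)])
        mean_f = sum(delivered) / k
        trajectory.append(pf_index(mean_f, k, params))
        if trajectory[-1] >= target_pfi:
            stopped = "target_reached"
            break

    return AblationRun(
        target_pfi=float(target_pfi),
        force_trace=delivered,
        applications_delivered=len(trajectory),
        pfi_trajectory=trajectory,
        attained_pfi=trajectory[-1],
        stopped_reason=stopped,
    )


def cf_stratum(force_g: float) -> str:
    """Assign a contact force to its protocol stratum.

    [5, 25] g -> ``low``; (25, 50] -> ``high``; (50, 80] -> ``very_high``;
    forces below 5 g or above 80 g -> ``out_of_range`` (excluded from
    analyses).  Negative forces are a caller error.
    """
    f = float(force_g)
    if not math.isfinite(f) or f < 0:
        raise ValueError(f"contact force must be finite and non-negative, got {force_g}")
    if f < FORCE_MIN_G or f > FORCE_MAX_G:
        return "out_of_range"
    if f <= 25.0:
        return "low"
    if f <= 50.0:
        return "high"
    return "very_high"


def pfi_stratum(intended_target: float) -> int:
    """Validate and return an intended PF-index target label.

    Stratum membership in the validation study is by *intended* target
    (300, 450 or 600), never by the attained value — the attained ranges
    overlap across strata.
    """
    try:
        t = int(intended_target)
    except (TypeError, ValueError):
        t = None
    if t is None or t != intended_target or t not in PFI_TARGETS:
        raise ValueError(
            f"intended PF index target must be one of {PFI_TARGETS}, got {intended_target}"
        )
    return t
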