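"""End-to-end orchestration of the two study arms.

``run_characterization`` reproduces the structure of the dose/force
characterization analysis: exclusion rules, dose- and CF-strata summary
tables, CF-only regressions, the dose-by-CF mean-depth surface, the
width-vs-dose profile, ANOVA, and the index-parameter fit.

``run_validation`` reproduces the index-evaluation analysis: PFI-strata
summaries, the PFI-vs-CF and depth-vs-(PFI/100) regressions, the
per-lesion observed-vs-expected table with ±2 mm band membership, and the
prediction-accuracy fraction.

``run_titration_experiment`` simulates the titration protocol across the
intended targets and CF strata and reports each target's attainability.

Reports are plain JSON-serializable dicts (schema-versioned) plus optional
Markdown renderings; figure analogs are emitted as tabular data, never
images.
"""

from __future__ import annotations

import copy
import dataclasses
import json
from dataclasses import dataclass

import numpy as np

from . import __version__ as _pkg_version
from . import studydata as sd
from .datagen import (
    CharGenConfig,
    ValidationGenConfig,
    default_char_config,
    default_index_parameters,
    default_validation_config,
    generate_characterization_lesions,
    generate_validation_lesions,
    substream,
)
from .fitting import fit_index_parameters
from .index import CF_STRATA_BOUNDS, PFI_TARGETS, IndexParameters, cf_stratum, simulate_titration
from .stats import (
    mad_outlier_flags,
    ols_fit,
    one_way_anova,
    prediction_accuracy,
    summarize_strata,
)

__all__ = [
    "PipelineConfig",
    "PipelineError",
    "run_characterization",
    "run_validation",
    "run_titration_experiment",
    "apply_characterization_exclusions",
    "report_to_markdown",
]

REPORT_SCHEMA_VERSION = 1


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    """Seed plus per-stage options; serializes round-trip to JSON."""

    seed: int
    n_char_lesions: int = sd.CHAR_N_LESIONS
    validation_mode: str = "B_strata"
    mad_k: float = 3.0
    accuracy_tolerance_mm: float = sd.VALIDATION_ACCURACY_TOL_MM
    max_applications: int = sd.PROTOCOL_MAX_APPLICATIONS
    titration_sessions_per_cell: int = 20

    def to_json(self, **kw) -> str:
        return json.dumps(dataclasses.asdict(self), **kw)

    @classmethod
    def from_json(cls, s: str) -> "PipelineConfig":
        return cls(**json.loads(s))


def _provenance(config: PipelineConfig, stage: str) -> dict:
    return {
        "schema_version": REPORT_SCHEMA_VERSION,
        "package_version": _pkg_version,
        "stage": stage,
        "config": dataclasses.asdict(config),
    }


# --------------------------------------------------------------------------
# Exclusion rules
# --------------------------------------------------------------------------


def apply_characterization_exclusions(lesions, mad_k: float = 3.0):
    """Apply the characterization exclusion rules, returning new records.

    Rules, in order: contact force outside the supported 5-80 g range;
    transmural lesions (depth censored by the wall); depth outliers per
    dose group by the scaled-MAD rule.  Already-excluded records keep
    their original reason.  Returns (records, accounting) where accounting
    reconciles n_input = n_analyzed + n_excluded by reason.
    """
    records = [copy.copy(r) for r in lesions]
    for r in records:
        if r.excluded:
            continue
        if cf_stratum(r.mean_cf_g) == "out_of_range":
            r.excluded, r.exclusion_reason = True, "cf_out_of_range"
        elif r.transmural:
            r.excluded, r.exclusion_reason = True, "transmural"

    candidates = [r for r in records if not r.excluded]
    if candidates:
        flags = mad_outlier_flags(
            [r.depth_mm for r in candidates],
            [r.n_applications for r in candidates],
            k=mad_k,
        )
        for r, f in zip(candidates, flags):
            if f:
                r.excluded, r.exclusion_reason = True, "outlier"

    by_reason: dict[str, int] = {}
    for r in records:
        if r.excluded:
            by_reason[r.exclusion_reason] = by_reason.get(r.exclusion_reason, 0) + 1
    accounting = {
        "n_input": len(records),
        "n_analyzed": sum(1 for r in records if not r.excluded),
        "n_excluded": sum(by_reason.values()),
        "excluded_by_reason": by_reason,
    }
    assert accounting["n_input"] == accounting["n_analyzed"] + accounting["n_excluded"]
    return records, accounting


# --------------------------------------------------------------------------
# Part 1: characterization
# --------------------------------------------------------------------------


def run_characterization(
    config: PipelineConfig,
    lesions=None,
    gen_config: CharGenConfig | None = None,
) -> dict:
    """Characterization analysis on given, or freshly generated, lesions."""
    if lesions is None:
        if gen_config is None:
            gen_config = default_char_config(config.seed, config.n_char_lesions)
        lesions = generate_characterization_lesions(gen_config)
    records, accounting = apply_characterization_exclusions(lesions, mad_k=config.mad_k)
    analyzed = [r for r in records if not r.excluded]
    if not analyzed:
        raise PipelineError("no lesions remain after exclusions")

    depth = np.array([r.depth_mm for r in analyzed])
    width = np.array([r.width_mm for r in analyzed])
    force = np.array([r.mean_cf_g for r in analyzed])
    doses = np.array([r.n_applications for r in analyzed])

    dose_depth = summarize_strata(analyzed, "dose", "depth")
    dose_width = summarize_strata(analyzed, "dose", "width")
    cf_depth = summarize_strata(analyzed, "cf_stratum", "depth")
    cf_width = summarize_strata(analyzed, "cf_stratum", "width")

    # dose x CF mean-depth surface (figure analog)
    surface = []
    for d in sorted(set(doses.tolist())):
        for lab in CF_STRATA_BOUNDS:
            mask = (doses == d) & np.array([cf_stratum(f) == lab for f in force])
            if mask.any():
                surface.append(
                    {"dose": int(d), "cf_stratum": lab,
                     "n": int(mask.sum()), "mean_depth_mm": float(depth[mask].mean())}
                )
    width_profile = [
        {"dose": int(s.group_label), "n": s.n, "mean_width_mm": s.mean, "sd": s.sd}
        for s in dose_width
        if s.group_label != "pooled"
    ]

    anova_dose = one_way_anova([depth[doses == d] for d in sorted(set(doses.tolist()))])
    cf_labels = np.array([cf_stratum(f) for f in force])
    anova_cf = one_way_anova(
        [depth[cf_labels == lab] for lab in CF_STRATA_BOUNDS if (cf_labels == lab).any()]
    )

    fit = fit_index_parameters(records)

    return {
        "provenance": _provenance(config, "characterization"),
        "accounting": accounting,
        "summaries": {
            "depth_by_dose": [s.to_dict() for s in dose_depth],
            "width_by_dose": [s.to_dict() for s in dose_width],
            "depth_by_cf_stratum": [s.to_dict() for s in cf_depth],
            "width_by_cf_stratum": [s.to_dict() for s in cf_width],
        },
        "regressions": {
            "depth_on_cf": ols_fit(force, depth).to_dict(),
            "width_on_cf": ols_fit(force, width).to_dict(),
        },
        "dose_cf_surface": surface,
        "width_dose_profile": width_profile,
        "anova": {
            "depth_across_dose": {"F": anova_dose[0], "p": anova_dose[1]},
            "depth_across_cf_strata": {"F": anova_cf[0], "p": anova_cf[1]},
        },
        "index_fit": fit.to_dict(),
    }


# --------------------------------------------------------------------------
# Part 2: validation
# --------------------------------------------------------------------------


def run_validation(
    config: PipelineConfig,
    lesions=None,
    gen_config: ValidationGenConfig | None = None,
) -> dict:
    """Validation analysis on given, or freshly generated, lesions."""
    if lesions is None:
        if gen_config is None:
            gen_config = default_validation_config(config.validation_mode, config.seed)
        lesions = generate_validation_lesions(gen_config)
    analyzed = [r for r in lesions if not r.excluded]
    if not analyzed:
        raise PipelineError("no analyzable validation lesions")
    if any(r.attained_pfi is None for r in analyzed):
        raise PipelineError("validation lesions must carry attained_pfi")

    pfi = np.array([r.attained_pfi for r in analyzed])
    depth = np.array([r.depth_mm for r in analyzed])
    force = np.array([r.mean_cf_g for r in analyzed])
    targets = np.array([r.intended_pfi_target for r in analyzed])

    frac, hits, n = prediction_accuracy(analyzed, config.accuracy_tolerance_mm)
    band = [
        {
            "lesion_id": r.lesion_id,
            "intended_target": r.intended_pfi_target,
            "attained_pfi": r.attained_pfi,
            "observed_depth_mm": r.depth_mm,
            "expected_depth_mm": r.attained_pfi / 100.0,
            "within_band": bool(
                abs(r.depth_mm - r.attained_pfi / 100.0) <= config.accuracy_tolerance_mm
            ),
        }
        for r in analyzed
    ]
    anova = one_way_anova([depth[targets == t] for t in PFI_TARGETS if (targets == t).any()])

    return {
        "provenance": _provenance(config, "validation"),
        "accounting": {
            "n_input": len(lesions),
            "n_analyzed": len(analyzed),
            "n_excluded": len(lesions) - len(analyzed),
        },
        "summaries": {
            "pfi_by_stratum": [s.to_dict() for s in summarize_strata(analyzed, "pfi_stratum", "pfi")],
            "depth_by_stratum": [s.to_dict() for s in summarize_strata(analyzed, "pfi_stratum", "depth")],
        },
        "regressions": {
            "pfi_on_cf": ols_fit(force, pfi).to_dict(),
            "depth_on_expected_depth": ols_fit(pfi / 100.0, depth).to_dict(),
        },
        "accuracy": {
            "tolerance_mm": config.accuracy_tolerance_mm,
            "fraction": frac,
            "numerator": hits,
            "denominator": n,
        },
        "observed_vs_expected": band,
        "anova": {"depth_across_pfi_strata": {"F": anova[0], "p": anova[1]}},
    }


# --------------------------------------------------------------------------
# Titration protocol simulation
# --------------------------------------------------------------------------


def run_titration_experiment(
    config: PipelineConfig,
    params: IndexParameters | None = None,
) -> dict:
    """Simulate titration sessions across targets and CF strata.

    For each (intended target, CF stratum) cell, per-application forces are
    drawn uniformly within the stratum's range; delivery follows the
    foot-pedal rule (stop at the first application where the running index
    reaches the target) capped at the protocol's application limit.
    """
    if params is None:
        params = default_index_parameters()
    if params is None:
        raise PipelineError("index parameters unavailable; run the fit step first")

    cells = []
    attainability: dict[int, list[bool]] = {t: [] for t in PFI_TARGETS}
    for target in PFI_TARGETS:
        for lab, (lo, hi) in CF_STRATA_BOUNDS.items():
            rng = substream(config.seed, f"titration:{target}:{lab}")
            attained, reached, apps = [], [], []
            for _ in range(config.titration_sessions_per_cell):
                trace = rng.uniform(lo, hi, size=config.max_applications)
                run = simulate_titration(target, trace, params, config.max_applications)
                attained.append(run.attained_pfi)
                reached.append(run.stopped_reason == "target_reached")
                apps.append(run.applications_delivered)
            attainability[target].extend(reached)
            a = np.array(attained)
            cells.append(
                {
                    "target": target,
                    "cf_stratum": lab,
                    "n_sessions": len(attained),
                    "attained_mean": float(a.mean()),
                    "attained_sd": float(a.std(ddof=1)),
                    "attained_min": float(a.min()),
                    "attained_max": float(a.max()),
                    "mean_applications": float(np.mean(apps)),
                    "fraction_reached": float(np.mean(reached)),
                }
            )
    return {
        "provenance": _provenance(config, "titration"),
        "params": params.to_dict(),
        "cells": cells,
        "target_attainability": {
            str(t): float(np.mean(v)) for t, v in attainability.items()
        },
    }


# --------------------------------------------------------------------------
# Rendering
# --------------------------------------------------------------------------


def _md_table(rows: list[dict], columns: list[str]) -> str:
    head = "| " + " | ".join(columns) + " |"
    sep = "|" + "|".join("---" for _ in columns) + "|"
    body = [
        "| " + " | ".join(
            f"{row[c]:.2f}" if isinstance(row[c], float) else str(row[c]) for c in columns
        ) + " |"
        for row in rows
    ]
    return "\n".join([head, sep] + body)


def report_to_markdown(report: dict) -> str:
    """Human-readable tables mirroring the study's summary-table layout."""
    stage = report["provenance"]["stage"]
    out = [f"# {stage.capitalize()} report", ""]
    if "summaries" in report:
        for name, rows in report["summaries"].items():
            out += [f"## {name}", "", _md_table(rows, ["group_label", "n", "mean", "sd", "min", "max"]), ""]
    if "regressions" in report:
        out.append("## Regressions\n")
        for name, reg in report["regressions"].items():
            out.append(
                f"- {name}: y = {reg['intercept']:.3f} + {reg['slope']:.4f}x; "
                f"r² = {reg['r2']:.2f}; p = {reg['p_slope']:.2g}; n = {reg['n']}"
            )
        out.append("")
    if "accuracy" in report:
        acc = report["accuracy"]
        out.append(
            f"Prediction accuracy (±{acc['tolerance_mm']:g} mm): "
            f"{acc['numerator']}/{acc['denominator']} ({100 * acc['fraction']:.0f}%)\n"
        )
    if "cells" in report:
        out += ["## Titration cells", "", _md_table(
            report["cells"],
            ["target", "cf_stratum", "n_sessions", "attained_mean", "attained_sd", "fraction_reached"],
        ), ""]
    return "\n".join(out)
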