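"""Synthetic generators, calibration-to-marginals, and table I/O."""

import dataclasses
import math

import numpy as np
import pytest

from pfindex import studydata as sd
from pfindex.datagen import (
    DesignMoments,
    IdentifiabilityError,
    LesionRecord,
    MarginalConstraint,
    ValidationGenConfig,
    calibrate_char_generator,
    characterization_diagnostics,
    default_char_config,
    default_validation_config,
    dataframe_to_lesions,
    derive_noise_sd_for_r2,
    generate_characterization_lesions,
    generate_validation_lesions,
    pfi_mixture_mean_variance,
    read_lesion_csv,
    write_lesion_csv,
)


# --------------------------------------------------------------------------
# Noise plumbing
# --------------------------------------------------------------------------


class TestNoiseFromR2:
    def test_closed_form_value_for_published_validation_design(self):
        # var of PFI/100 under the published strata mixture
        mean, var = pfi_mixture_mean_variance()
        assert mean == pytest.approx(4.24, abs=0.01)
        assert var == pytest.approx(1.088, abs=0.002)
        sigma = derive_noise_sd_for_r2(0.640, var, 0.66)
        assert sigma == pytest.approx(0.479, abs=0.002)

    def test_perfect_fit_limit_needs_no_noise(self):
        assert derive_noise_sd_for_r2(0.640, 1.0, 1 - 1e-12) == pytest.approx(0.0, abs=1e-5)

    def test_sigma_proportional_to_beta(self):
        s1 = derive_noise_sd_for_r2(0.5, 2.0, 0.4)
        s2 = derive_noise_sd_for_r2(1.0, 2.0, 0.4)
        assert s2 == pytest.approx(2 * s1)

    @pytest.mark.parametrize("r2", [0.0, 1.0, -0.5, 1.5])
    def test_invalid_r2_rejected(self, r2):
        with pytest.raises(ValueError):
            derive_noise_sd_for_r2(0.6, 1.0, r2)


# --------------------------------------------------------------------------
# Validation generator
# --------------------------------------------------------------------------


class TestValidationGenerator:
    def test_published_strata_counts(self):
        lesions = generate_validation_lesions(default_validation_config("B_strata", 5))
        assert len(lesions) == 73
        counts = {t: sum(1 for r in lesions if r.intended_pfi_target == t)
                  for t in (300, 450, 600)}
        assert counts == {300: 29, 450: 23, 600: 21}

    def test_same_seed_reproduces_identical_tables(self, tmp_path):
        a = generate_validation_lesions(default_validation_config("A_linear", 11))
        b = generate_validation_lesions(default_validation_config("A_linear", 11))
        assert a == b
        pa, pb = tmp_path / "a.csv", tmp_path / "b.csv"
        write_lesion_csv(a, pa)
        write_lesion_csv(b, pb)
        assert pa.read_bytes() == pb.read_bytes()

    def test_mode_a_with_zero_noise_is_exactly_linear(self):
        cfg = default_validation_config("A_linear", 3)
        cfg.sigma = 0.0
        for r in generate_validation_lesions(cfg):
            assert r.depth_mm == pytest.approx(0.923 + 0.640 * r.attained_pfi / 100.0)

    def test_mode_b_depth_independent_of_beta(self):
        cfg = default_validation_config("B_strata", 3)
        cfg.beta1 = 99.0  # ignored in mode B
        lesions = generate_validation_lesions(cfg)
        assert max(r.depth_mm for r in lesions) < 12.0

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            ValidationGenConfig(
                mode="A_linear", strata=((300, 29, 307.0, 0.0, 2.86, 0.67),),
                beta0=0.9, beta1=0.64, sigma=0.5, seed=0,
            )
        with pytest.raises(ValueError):
            ValidationGenConfig(
                mode="C_bogus", strata=((300, 29, 307.0, 21.0, 2.86, 0.67),),
                beta0=0.9, beta1=0.64, sigma=0.5, seed=0,
            )


# --------------------------------------------------------------------------
# Characterization generator
# --------------------------------------------------------------------------


class TestCharacterizationGenerator:
    def test_doses_as_equally_distributed_as_possible(self):
        lesions = generate_characterization_lesions(default_char_config(2))
        assert len(lesions) == 111
        counts = sorted(
            sum(1 for r in lesions if r.n_applications == d) for d in (3, 6, 9, 12)
        )
        assert counts == [27, 28, 28, 28]

    def test_zero_noise_depths_identical_at_fixed_conditions(self):
        cfg = default_char_config(4, n_lesions=40)
        cfg = dataclasses.replace(
            cfg, sigma_depth=0.0,
            cf_strata_weights={"low": 1.0, "high": 0.0, "very_high": 0.0},
            cf_ranges={"low": (32.0, 32.0), "high": (26.0, 50.0), "very_high": (51.0, 80.0)},
            dose_levels=(12,), dose_weights=(1.0,),
        )
        depths = {r.depth_mm for r in generate_characterization_lesions(cfg)}
        assert len(depths) == 1

    def test_sampler_reproduces_study_mean_force(self):
        cfg = default_char_config(6, n_lesions=10_000)
        forces = np.array(
            [r.mean_cf_g for r in generate_characterization_lesions(cfg)]
        )
        assert forces.mean() == pytest.approx(32.4, abs=0.5)
        assert 15.0 < forces.std() < 22.0

    def test_thin_wall_produces_transmural_exclusions(self):
        cfg = dataclasses.replace(default_char_config(8, n_lesions=60), wall_thickness_mm=3.0)
        lesions = generate_characterization_lesions(cfg)
        trans = [r for r in lesions if r.transmural]
        assert trans, "3 mm wall should censor many lesions"
        assert all(r.excluded and r.exclusion_reason == "transmural" for r in trans)
        assert all(r.depth_mm == 3.0 for r in trans)

    def test_empty_dose_set_rejected(self):
        cfg = default_char_config(1)
        with pytest.raises(ValueError):
            dataclasses.replace(cfg, dose_levels=(), dose_weights=())


# --------------------------------------------------------------------------
# Calibration
# --------------------------------------------------------------------------


def _cell_mean_constraints(params, sigma, design):
    """Full-rank constraint set: every (CF stratum, dose) cell mean plus
    the overall SD, with implied values computed from the truth."""
    theta = np.array([params.b0, params.b1, params.c0, params.c1, sigma])
    cons = []
    for lab, _ in design.cf_weights:
        for d in design.dose_levels:
            cons.append(
                MarginalConstraint(
                    "cell_mean", design.implied_stat("cell_mean", (lab, d), theta), (lab, d)
                )
            )
    cons.append(MarginalConstraint("overall_sd", design.implied_stat("overall_sd", None, theta)))
    return cons


class TestCalibration:
    def test_round_trip_recovers_known_parameters(self):
        from pfindex.index import IndexParameters

        truth = IndexParameters(b0=1.1, b1=0.008, c0=0.6, c1=0.007)
        design = DesignMoments.study_default()
        cons = _cell_mean_constraints(truth, 0.9, design)
        cal = calibrate_char_generator(cons, design)
        for got, want in zip(
            (cal.params.b0, cal.params.b1, cal.params.c0, cal.params.c1, cal.sigma_depth),
            (truth.b0, truth.b1, truth.c0, truth.c1, 0.9),
        ):
            assert got == pytest.approx(want, rel=0.01)

    def test_underdetermined_sets_rejected(self):
        with pytest.raises(IdentifiabilityError):
            calibrate_char_generator([MarginalConstraint("overall_mean", 3.6)])
        # five constraints but no mean-rank: dispersion-only set
        with pytest.raises(IdentifiabilityError):
            calibrate_char_generator([MarginalConstraint("overall_sd", 1.2)] * 5)

    def test_published_mean_and_sd_set_implies_overall_mean_near_3_6(self):
        cons = [
            MarginalConstraint("dose_mean", 2.48, 3),
            MarginalConstraint("dose_mean", 4.52, 12),
            MarginalConstraint("cf_stratum_mean", 2.98, "low"),
            MarginalConstraint("cf_stratum_mean", 3.82, "high"),
            MarginalConstraint("cf_stratum_mean", 4.23, "very_high"),
            MarginalConstraint("overall_sd", 1.2),
        ]
        cal = calibrate_char_generator(cons)
        design = DesignMoments.study_default()
        theta = np.array(
            [cal.params.b0, cal.params.b1, cal.params.c0, cal.params.c1, cal.sigma_depth]
        )
        assert design.implied_stat("overall_mean", None, theta) == pytest.approx(3.6, abs=0.1)

    def test_default_calibration_hits_its_contracted_statistics(self):
        from pfindex.datagen import _default_calibration

        diag = characterization_diagnostics(_default_calibration())
        for key, tol in [
            ("depth_mean_dose_x3", 0.1), ("depth_mean_dose_x12", 0.1),
            ("depth_cf_slope", 0.005), ("depth_cf_r2", 0.01),
            ("depth_overall_mean", 0.1),
        ]:
            assert diag[key]["implied"] == pytest.approx(diag[key]["published"], abs=tol), key

    def test_width_model_reproduces_published_width_moments(self):
        cfg = default_char_config(0)
        design = DesignMoments.study_default()
        wm = cfg.width_model
        mean = (
            wm.w0 + wm.w_log * design.logdose_plateau_mean(wm.plateau_n)
            + wm.w_force * design.force_mean
        )
        var = (
            wm.sigma_width**2 + wm.w_force**2 * design.force_var
            + wm.w_log**2 * design.logdose_plateau_var(wm.plateau_n)
        )
        assert mean == pytest.approx(sd.CHAR_WIDTH_MEAN, abs=1e-9)
        assert math.sqrt(var) == pytest.approx(sd.CHAR_WIDTH_SD, abs=1e-9)


# --------------------------------------------------------------------------
# Table I/O
# --------------------------------------------------------------------------


class TestTableIO:
    def test_csv_round_trip_preserves_records(self, tmp_path):
        lesions = generate_validation_lesions(default_validation_config("B_strata", 9))
        path = tmp_path / "lesions.csv"
        write_lesion_csv(lesions, path, provenance={"seed": 9})
        again = read_lesion_csv(path)
        assert len(again) == len(lesions)
        for a, b in zip(lesions, again):
            assert a.lesion_id == b.lesion_id
            assert a.depth_mm == pytest.approx(b.depth_mm)
            assert a.intended_pfi_target == b.intended_pfi_target
        assert (tmp_path / "lesions.csv.provenance.json").exists()

    def test_missing_columns_rejected(self):
        import pandas as pd

        with pytest.raises(ValueError, match="missing columns"):
            dataframe_to_lesions(pd.DataFrame({"depth_mm": [1.0]}))

    def test_record_invariants_enforced(self):
        with pytest.raises(ValueError):
            LesionRecord(
                lesion_id="X", animal_id="A", chamber="RV", mean_cf_g=30.0,
                n_applications=3, attained_pfi=300.0, depth_mm=3.0, width_mm=10.0,
                excluded=True, exclusion_reason=None,
            )
        with pytest.raises(ValueError):
            LesionRecord(
                lesion_id="X", animal_id="A", chamber="RV", mean_cf_g=30.0,
                n_applications=0, attained_pfi=300.0, depth_mm=3.0, width_mm=10.0,
            )
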