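"""Published summary statistics of the two swine ventricular lesion studies.

These are the marginal statistics the synthetic generators are required to
emulate: the raw per-lesion tables were never deposited, so the printed
summaries are the only quantitative anchor.  Everything downstream
(generator calibration, acceptance checks) treats these numbers as inputs.

Part 1 ("characterization", 111 lesions, 11 swine): predefined doses of
x3/x6/x9/x12 PFA applications delivered while holding contact force in
low/high/very-high strata; lesion depth and width measured at necropsy.

Part 2 ("validation", 73 lesions, 6 swine): titration to intended PF-index
targets 300/450/600; attained index and depth recorded per lesion.
"""

from __future__ import annotations

# --------------------------------------------------------------------------
# Part 1 - characterization
# --------------------------------------------------------------------------

CHAR_N_LESIONS = 111
CHAR_DOSE_LEVELS = (3, 6, 9, 12)

#: share of analyzed lesions per CF stratum as printed (sums to 96%; the
#: remainder was delivered above 80 g and excluded from analyses).
CHAR_CF_STRATA_PCT = {"low": 40.0, "high": 41.0, "very_high": 15.0}

CHAR_CF_MEAN_G = 32.0
CHAR_CF_SD_G = 17.0

#: depth marginal means (mm) printed in the Results text.
CHAR_DEPTH_MEAN_BY_DOSE = {3: 2.48, 12: 4.52}
CHAR_DEPTH_SD_BY_DOSE = {3: 0.90, 12: 1.09}
CHAR_DEPTH_MEAN_BY_CF = {"low": 2.98, "high": 3.82, "very_high": 4.23}
CHAR_DEPTH_SD_BY_CF = {"low": 0.98, "high": 1.21, "very_high": 1.30}

CHAR_DEPTH_MEAN = 3.6
CHAR_DEPTH_SD = 1.2
CHAR_WIDTH_MEAN = 12.2
CHAR_WIDTH_SD = 3.3

#: depth-on-CF and width-on-CF simple regressions (CF in grams).
CHAR_DEPTH_CF_SLOPE = 0.0209
CHAR_DEPTH_CF_INTERCEPT = 2.882
CHAR_DEPTH_CF_R2 = 0.08
CHAR_WIDTH_CF_SLOPE = 0.0422
CHAR_WIDTH_CF_INTERCEPT = 10.633
CHAR_WIDTH_CF_R2 = 0.04

#: width grows slightly with dose up to 9 applications, then plateaus.
CHAR_WIDTH_PLATEAU_N = 9

# --------------------------------------------------------------------------
# Part 2 - validation
# --------------------------------------------------------------------------

VALIDATION_N_LESIONS = 73

#: per intended-target stratum: n, attained-PFI mean/SD, depth mean/SD (mm).
VALIDATION_STRATA = {
    300: {"n": 29, "pfi_mean": 307.0, "pfi_sd": 21.0, "depth_mean": 2.86, "depth_sd": 0.67},
    450: {"n": 23, "pfi_mean": 460.0, "pfi_sd": 24.0, "depth_mean": 3.92, "depth_sd": 0.73},
    600: {"n": 21, "pfi_mean": 547.0, "pfi_sd": 34.0, "depth_mean": 4.41, "depth_sd": 0.94},
}

#: depth (mm) on PFI/100 regression and its fit quality.
VALIDATION_BETA0 = 0.923
VALIDATION_BETA1 = 0.640
VALIDATION_R2 = 0.66

VALIDATION_PFI_MEAN = 424.0
VALIDATION_PFI_SD = 105.0
VALIDATION_DEPTH_MEAN = 3.6
VALIDATION_DEPTH_SD = 1.0

#: fraction of lesions whose depth was predicted within +/-2 mm by PFI/100.
VALIDATION_ACCURACY = 69 / 73
VALIDATION_ACCURACY_TOL_MM = 2.0

#: CF strata occupancy in the validation lesions (counts over 73).
VALIDATION_CF_STRATA_COUNTS = {"low": 29, "high": 30, "very_high": 14}

#: protocol cap on applications per lesion.
PROTOCOL_MAX_APPLICATIONS = 12
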