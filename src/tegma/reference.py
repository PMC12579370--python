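"""Published study constants: fitted channel equations and clinical targets.

These are the fitted mean structures reported for a 2,349-run adult cardiac
surgery cohort (TEG6s, cardiopulmonary bypass) relating the citrated rapid
TEG reaction time (CRT-R, minutes) to later-resulting parameters. They serve
two roles in this package: as generating truth for the synthetic cohort, and
as the reference models behind the cutoff/conversion convenience entry
points.
"""

from __future__ import annotations

from .association import ExpDecayModel, LinearModel

#: CRT-R -> CFF-MA (functional-fibrinogen maximum amplitude, mm)
CFF_MA_DECAY = ExpDecayModel(a=29.9054, b=0.7345, c=0.3548)
#: CRT-R -> CRT-MA (rapid-TEG maximum amplitude, mm)
CRT_MA_DECAY = ExpDecayModel(a=39.4557, b=0.5034, c=27.5760)
#: CRT-R -> CKH-MA (kaolin-heparinase maximum amplitude, mm)
CKH_MA_DECAY = ExpDecayModel(a=42.0377, b=0.5107, c=25.0521)
#: CRT-R -> CKH-R (kaolin-heparinase reaction time, min); increasing, a < 0
CKH_R_DECAY = ExpDecayModel(a=-8.4209, b=0.8974, c=11.7798)

#: CRT-R (min) as a linear function of TEG-ACT (s); the device derives ACT
#: from the reaction time, so the relationship is essentially exact.
ACT_TO_CRT_R_LINE = LinearModel(slope=0.0107, intercept=-0.5397)

#: residual scale (RMSE, channel units) of each published fit — used as the
#: default noise standard deviation when simulating that channel
CHANNEL_RMSE = {
    "cff_ma_mm": 5.0788,
    "crt_ma_mm": 6.5485,
    "ckh_ma_mm": 7.4195,
    "ckh_r_min": 3.9846,
    "teg_act_s": 0.0,
}

#: clinically anchored maximum-amplitude targets (mm): CRT-MA below 48 mm
#: flags globally weak clots; CFF-MA below 12 mm flags fibrinogen-deficient
#: clot strength
MA_TARGET_CRT = 48.0
MA_TARGET_CFF = 12.0

#: observed TEG-ACT range (s) in the study cohort; conversions outside it
#: are extrapolations and trigger a warning
ACT_PLAUSIBLE_RANGE = (60.0, 199.0)

#: CRT-R exclusion threshold (min): five times the upper limit of normal;
#: larger values are treated as assay outliers
CRT_R_MAX = 5.5
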