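"""Class-effect profiles parameterising the synthetic cohort.

SAM means and standard deviations are the published descriptive
statistics of the study cohort (n = 25) for each of the eight film-clip
classes.  The autonomic effect parameters (heart-rate offset, RR-interval
variability scaling, phasic electrodermal event rate, tonic drift,
respiration rate, temperature drift) are generator conventions: the
original recordings report no per-class parameter table, so these ship as
documented defaults sized to give a clearly-above-chance but far from
perfect four-class classification problem at ``effect_size = 1``
(roughly 50 % leave-one-out accuracy, mirroring the regime the real data
sits in).  They are a calibration aid, not an empirical claim.
"""

from __future__ import annotations

from dataclasses import dataclass

from .exceptions import InvalidArgumentError
from .types import ALL_CLASSES

#: baseline (rest) values that class effects perturb
BASELINE_HR_BPM = 70.0
BASELINE_SCL_US = 5.0
BASELINE_TEMP_C = 33.0
#: paced-breathing rate followed during every 40-s baseline epoch
BASELINE_RESP_BPM = 14.0
#: neutral phasic electrodermal event rate at rest, events/min
BASELINE_SCR_RATE = 3.0


@dataclass(frozen=True)
class ClassEffectProfile:
    """Autonomic modulation and SAM distribution for one stimulus class.

    Attributes
    ----------
    delta_hr : float
        Heart-rate offset from the subject's resting rate, beats/min.
    hrv_scale : float
        Multiplier on RR-interval variability (1 = resting variability).
    scr_rate : float
        Phasic skin-conductance events per minute, >= 0.
    scl_slope : float
        Tonic skin-conductance drift, microsiemens/min.
    resp_rate : float
        Breathing rate during the stimulus, breaths/min, > 0.
    st_slope : float
        Skin-temperature drift, deg C/min.
    sam_means, sam_sds : tuple[float, float, float]
        Normal parameters of the (arousal, valence, dominance) report.
    """

    delta_hr: float
    hrv_scale: float
    scr_rate: float
    scl_slope: float
    resp_rate: float
    st_slope: float
    sam_means: tuple[float, float, float]
    sam_sds: tuple[float, float, float]

    def __post_init__(self) -> None:
        if self.resp_rate <= 0:
            raise InvalidArgumentError("resp_rate must be positive")
        if self.scr_rate < 0:
            raise InvalidArgumentError("scr_rate must be non-negative")
        if not all(1.0 <= m <= 9.0 for m in self.sam_means):
            raise InvalidArgumentError("sam_means must lie in [1, 9]")
        if not all(s >= 0 for s in self.sam_sds):
            raise InvalidArgumentError("sam_sds must be non-negative")


# (arousal, valence, dominance) — published cohort descriptive statistics.
_SAM_TABLE: dict[str, tuple[tuple[float, float, float], tuple[float, float, float]]] = {
    "anima": ((5.320, 5.880, 5.560), (1.520, 1.590, 2.022)),
    "animus": ((6.400, 3.680, 4.360), (1.893, 1.520, 2.119)),
    "hero": ((5.720, 4.520, 6.040), (1.768, 2.104, 2.189)),
    "shadow": ((6.080, 5.000, 5.08), (2.080, 2.121, 2.290)),
    "active-pleasant": ((4.160, 7.400, 6.640), (2.511, 1.472, 1.753)),
    "active-unpleasant": ((6.600, 3.040, 3.160), (2.363, 1.719, 2.444)),
    "passive-pleasant": ((4.360, 8.320, 7.200), (2.691, 0.748, 1.658)),
    "passive-unpleasant": ((4.120, 4.840, 4.640), (2.571, 2.075, 2.139)),
}

# Autonomic modulation defaults: (delta_hr, hrv_scale, scr_rate, scl_slope,
# resp_rate, st_slope).  Directions follow the usual autonomic signatures:
# high-arousal / threat classes raise HR, sympathetic EDA activity and
# respiration while suppressing vagally mediated HRV and peripheral
# temperature; calm pleasant classes do the opposite.
_ANS_TABLE: dict[str, tuple[float, float, float, float, float, float]] = {
    "anima": (0.6, 1.03, 3.3, 0.06, 14.00, -0.003),
    "animus": (1.8, 0.94, 4.5, 0.15, 14.90, -0.009),
    "hero": (1.2, 1.00, 3.9, 0.10, 14.45, 0.000),
    "shadow": (0.3, 0.97, 3.6, 0.05, 13.70, -0.006),
    "active-pleasant": (1.10, 1.00, 3.9, 0.09, 14.55, 0.002),
    "active-unpleasant": (1.55, 0.94, 4.3, 0.12, 14.90, -0.009),
    "passive-pleasant": (-0.20, 1.04, 2.8, 0.01, 13.65, 0.004),
    "passive-unpleasant": (0.00, 0.99, 3.0, 0.02, 13.90, -0.002),
}


def default_profiles() -> dict[str, ClassEffectProfile]:
    """The shipped per-class effect profiles for all eight classes."""
    out = {}
    for cls in ALL_CLASSES:
        dhr, hrv, scr, scl, resp, st = _ANS_TABLE[cls]
        means, sds = _SAM_TABLE[cls]
        out[cls] = ClassEffectProfile(
            delta_hr=dhr, hrv_scale=hrv, scr_rate=scr, scl_slope=scl,
            resp_rate=resp, st_slope=st, sam_means=means, sam_sds=sds,
        )
    return out


def scale_profile(
    profile: ClassEffectProfile, effect_size: float
) -> ClassEffectProfile:
    """Interpolate a profile between the neutral resting state and its
    full class effect.

    ``effect_size = 0`` collapses every class onto the shared resting
    parameters (a null cohort with no class-dependent structure);
    ``effect_size = 1`` applies the profile as-is.  SAM means shrink
    toward the neutral midpoint 5; SAM standard deviations are kept so a
    null cohort still produces dispersed, uninformative reports.
    """
    if not 0.0 <= effect_size <= 1.0:
        raise InvalidArgumentError("effect_size must lie in [0, 1]")
    e = effect_size
    return ClassEffectProfile(
        delta_hr=e * profile.delta_hr,
        hrv_scale=1.0 + e * (profile.hrv_scale - 1.0),
        scr_rate=BASELINE_SCR_RATE + e * (profile.scr_rate - BASELINE_SCR_RATE),
        scl_slope=e * profile.scl_slope,
        resp_rate=BASELINE_RESP_BPM + e * (profile.resp_rate - BASELINE_RESP_BPM),
        st_slope=e * profile.st_slope,
        sam_means=tuple(5.0 + e * (m - 5.0) for m in profile.sam_means),
        sam_sds=profile.sam_sds,
    )
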