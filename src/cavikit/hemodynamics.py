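"""Arterial-stiffness formula chain: PWV, beta, CAVI, beta0 and CAVI0.

The cardio-ankle vascular index (CAVI) is a heart-to-ankle stiffness
index built on the Bramwell--Hill relation between pulse wave velocity
(PWV) and arterial distensibility,

    CAVI = a * beta + b,      beta = 2 rho PWV^2 ln(SBP/DBP) / dP,

where ``dP = SBP - DBP`` (in Pa), ``rho`` is blood density and ``a``,
``b`` are device scaling constants.  CAVI0 re-references the index to a
fixed pressure ``Pref`` (conventionally 100 mmHg) so that, at fixed PWV,
it depends on diastolic pressure alone:

    CAVI0 = 2 rho PWV^2 / DBP - ln(DBP / Pref)     (DBP in Pa inside
                                                    the first term).

Every function here accepts scalars or NumPy arrays and returns floats
for scalar input.  Pressures are supplied in mmHg and converted to Pa
internally; PWV is in m/s, rho in kg/m^3, and the indexes are
dimensionless.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import (
    DegeneratePressureError,
    InvalidPressureError,
    InvalidTimingError,
    NegativeBetaError,
)

__all__ = [
    "MMHG_TO_PA",
    "PressurePair",
    "HemoConstants",
    "WaveTiming",
    "StiffnessIndices",
    "mmhg_to_pa",
    "pa_to_mmhg",
    "heart_ankle_pwv",
    "beta_from_pwv",
    "cavi_from_pwv",
    "cavi0_from_pwv",
    "cavi0_from_cavi",
    "beta0_from_beta",
    "pwv_from_cavi",
    "stiffness_from_timing",
]

#: Conversion factor from millimetres of mercury to pascal.
MMHG_TO_PA = 133.322


def mmhg_to_pa(p):
    """Convert a pressure (or pressure difference) from mmHg to Pa."""
    return np.multiply(p, MMHG_TO_PA)


def pa_to_mmhg(p):
    """Convert a pressure from Pa back to mmHg."""
    return np.divide(p, MMHG_TO_PA)


def _maybe_scalar(x):
    arr = np.asarray(x)
    return arr.item() if arr.ndim == 0 else arr


@dataclass(frozen=True)
class PressurePair:
    """Brachial systolic/diastolic pressures for one subject, in mmHg.

    Derived quantities follow the standard sphygmomanometric
    conventions: pulse pressure ``pp = sbp - dbp`` and mean arterial
    pressure ``map = dbp + pp/3``.
    """

    sbp: float
    dbp: float

    def __post_init__(self):
        sbp = np.asarray(self.sbp, dtype=float)
        dbp = np.asarray(self.dbp, dtype=float)
        if not (np.all(np.isfinite(sbp)) and np.all(np.isfinite(dbp))):
            raise InvalidPressureError("pressures must be finite")
        if np.any(dbp <= 0):
            raise InvalidPressureError("DBP must be positive")
        if np.any(sbp <= dbp):
            raise InvalidPressureError("SBP must exceed DBP")

    @property
    def pp(self):
        """Pulse pressure SBP - DBP (mmHg)."""
        return _maybe_scalar(np.asarray(self.sbp) - np.asarray(self.dbp))

    @property
    def map(self):
        """Mean arterial pressure DBP + PP/3 (mmHg)."""
        return _maybe_scalar(np.asarray(self.dbp) + np.asarray(self.pp) / 3.0)

    @property
    def delta_p(self):
        """Pulse pressure expressed in Pa, as used inside the formulas."""
        return _maybe_scalar(mmhg_to_pa(self.pp))


@dataclass(frozen=True)
class HemoConstants:
    """Device and physical constants of the stiffness formula chain.

    ``scale_a`` and ``offset_b`` are the proprietary linear scaling of
    the measuring device; the library defaults (a=1, b=0) yield the raw
    Bramwell--Hill beta.  ``rho`` is blood density in kg/m^3 and
    ``pref`` the reference pressure (mmHg) anchoring CAVI0.
    """

    scale_a: float = 1.0
    offset_b: float = 0.0
    rho: float = 1050.0
    pref: float = 100.0

    def __post_init__(self):
        if self.scale_a <= 0:
            raise InvalidPressureError("scale_a must be positive")
        if self.rho <= 0:
            raise InvalidPressureError("rho must be positive")
        if self.pref <= 0:
            raise InvalidPressureError("pref must be positive")


@dataclass(frozen=True)
class WaveTiming:
    """Pulse transit timing from aortic valve to ankle.

    ``tb`` is the time from the second heart sound to the dicrotic
    notch of the brachial waveform and ``tba`` the brachial-to-ankle
    delay; their sum is the total heart-to-ankle transit time over the
    path of length ``path_length`` metres.
    """

    path_length: float
    tb: float
    tba: float

    def __post_init__(self):
        if np.any(np.asarray(self.path_length) <= 0):
            raise InvalidTimingError("path_length must be positive")
        if np.any(np.asarray(self.tb) < 0) or np.any(np.asarray(self.tba) < 0):
            raise InvalidTimingError("transit times must be non-negative")

    @property
    def t_total(self):
        return _maybe_scalar(np.asarray(self.tb) + np.asarray(self.tba))


@dataclass(frozen=True)
class StiffnessIndices:
    """Bundle of the five stiffness quantities for one measurement."""

    pwv: float
    beta: float
    beta0: float
    cavi: float
    cavi0: float
    constants: HemoConstants = field(default_factory=HemoConstants)


def heart_ankle_pwv(timing: WaveTiming):
    """Heart-ankle pulse wave velocity: path length over total transit time."""
    t = np.asarray(timing.t_total, dtype=float)
    if np.any(t <= 0):
        raise InvalidTimingError("total transit time must be positive")
    return _maybe_scalar(np.asarray(timing.path_length) / t)


def beta_from_pwv(pressures: PressurePair, pwv, rho: float = 1050.0):
    """Bramwell--Hill stiffness parameter beta from PWV and pressures.

    beta = 2 rho PWV^2 ln(SBP/DBP) / (SBP - DBP), with the pressure
    difference in Pa.  Strictly increasing in PWV; zero at PWV = 0.
    """
    sbp = np.asarray(pressures.sbp, dtype=float)
    dbp = np.asarray(pressures.dbp, dtype=float)
    if np.any(sbp == dbp):
        raise DegeneratePressureError("SBP == DBP gives an indeterminate 0/0 ratio")
    pwv = np.asarray(pwv, dtype=float)
    if np.any(pwv < 0):
        raise InvalidPressureError("PWV must be non-negative")
    return _maybe_scalar(
        2.0 * rho * pwv**2 * np.log(sbp / dbp) / mmhg_to_pa(sbp - dbp)
    )


def cavi_from_pwv(pressures: PressurePair, pwv, constants: HemoConstants | None = None):
    """CAVI = a * beta + b with beta from :func:`beta_from_pwv`."""
    c = constants or HemoConstants()
    return _maybe_scalar(
        c.scale_a * np.asarray(beta_from_pwv(pressures, pwv, c.rho)) + c.offset_b
    )


def cavi0_from_pwv(dbp, pwv, rho: float = 1050.0, pref: float = 100.0):
    """Pressure-referenced index CAVI0 directly from DBP and PWV.

    CAVI0 = 2 rho PWV^2 / DBP_Pa - ln(DBP / Pref).  At fixed PWV the
    index is strictly decreasing in DBP, which is the mechanistic core
    of its age sensitivity in populations whose DBP declines with age.
    """
    dbp = np.asarray(dbp, dtype=float)
    if np.any(dbp <= 0):
        raise InvalidPressureError("DBP must be positive")
    if pref <= 0:
        raise InvalidPressureError("Pref must be positive")
    pwv = np.asarray(pwv, dtype=float)
    return _maybe_scalar(
        2.0 * rho * pwv**2 / mmhg_to_pa(dbp) - np.log(dbp / pref)
    )


def cavi0_from_cavi(cavi, pressures: PressurePair, constants: HemoConstants | None = None):
    """Convert a measured CAVI to CAVI0 without re-measuring PWV.

    CAVI0 = [(CAVI - b)/a] * (SBP/DBP - 1)/ln(SBP/DBP) - ln(DBP/Pref).

    This is the exact algebraic composition of the CAVI formula
    inverted for beta and substituted into the direct CAVI0 formula,
    so the result is independent of the device constants (a, b) used
    to produce the CAVI value.
    """
    c = constants or HemoConstants()
    sbp = np.asarray(pressures.sbp, dtype=float)
    dbp = np.asarray(pressures.dbp, dtype=float)
    if np.any(sbp == dbp):
        raise DegeneratePressureError("SBP == DBP gives an indeterminate ratio")
    beta = (np.asarray(cavi, dtype=float) - c.offset_b) / c.scale_a
    ratio = (sbp / dbp - 1.0) / np.log(sbp / dbp)
    return _maybe_scalar(beta * ratio - np.log(dbp / c.pref))


def beta0_from_beta(beta, dbp, pref: float = 100.0):
    """Pressure-normalized stiffness beta0 = beta - ln(DBP/Pref)."""
    dbp = np.asarray(dbp, dtype=float)
    if np.any(dbp <= 0) or pref <= 0:
        raise InvalidPressureError("DBP and Pref must be positive")
    return _maybe_scalar(np.asarray(beta, dtype=float) - np.log(dbp / pref))


def pwv_from_cavi(cavi, pressures: PressurePair, constants: HemoConstants | None = None):
    """Invert the CAVI formula back to the pulse wave velocity.

    Requires ``cavi >= offset_b`` (the implied beta must be
    non-negative).  Satisfies ``cavi_from_pwv(p, pwv_from_cavi(v, p))
    == v`` to numerical precision.
    """
    c = constants or HemoConstants()
    beta = (np.asarray(cavi, dtype=float) - c.offset_b) / c.scale_a
    if np.any(beta < 0):
        raise NegativeBetaError("CAVI below the device offset implies beta < 0")
    sbp = np.asarray(pressures.sbp, dtype=float)
    dbp = np.asarray(pressures.dbp, dtype=float)
    if np.any(sbp == dbp):
        raise DegeneratePressureError("SBP == DBP gives an indeterminate ratio")
    return _maybe_scalar(
        np.sqrt(beta * mmhg_to_pa(sbp - dbp) / (2.0 * c.rho * np.log(sbp / dbp)))
    )


def stiffness_from_timing(
    timing: WaveTiming,
    pressures: PressurePair,
    constants: HemoConstants | None = None,
) -> StiffnessIndices:
    """Full formula chain from raw transit times to all five indexes."""
    c = constants or HemoConstants()
    pwv = heart_ankle_pwv(timing)
    beta = beta_from_pwv(pressures, pwv, c.rho)
    return StiffnessIndices(
        pwv=pwv,
        beta=beta,
        beta0=beta0_from_beta(beta, pressures.dbp, c.pref),
        cavi=_maybe_scalar(c.scale_a * np.asarray(beta) + c.offset_b),
        cavi0=cavi0_from_pwv(pressures.dbp, pwv, c.rho, c.pref),
        constants=c,
    )
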