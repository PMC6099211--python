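"""Dosimeter calibration models and uncertainty propagation.

Implements the three dosimeter technologies used to validate the Monte
Carlo engine against measurement:

* radiochromic (GafChromic-type) film: dose(x) = a + b*x/ln(x) with
  x = net optical-reflectance change (netDeltaR), and a percent-uncertainty
  model u%(D) = a + b*exp(-D/c);
* LiF TLD chips: D_i = Q_i * K_calib / S_i (reading in nC, calibration
  factor in mGy/nC, per-chip sensitivity S_i);
* MOSFET dosimeters: D = mean(deltaV / CF) over repeated exposures.

Combined standard uncertainties (k = 1) are quadrature sums of Type A
components and Type B components specified as rectangular half-widths
(converted by a/sqrt(3)).  Calibrations are depth-specific: applying a
calibration at a different depth requires an explicit override, because
beam hardening changes the dosimeter response with depth.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GafCalib", "TLDCalib", "MOSFETCalib", "UncertaintyComponent",
    "fit_gaf_calibration", "gaf_dose", "gaf_uncertainty", "tld_dose",
    "mosfet_dose", "combine_uncertainty", "synth_readings",
    "DepthMismatchError",
]


class DepthMismatchError(ValueError):
    """Calibration applied at a depth it was not acquired for."""


def _check_depth(calib_depth, depth, override):
    if depth is not None and calib_depth is not None \
            and abs(depth - calib_depth) > 1e-9 and not override:
        raise DepthMismatchError(
            f"calibration for depth {calib_depth} cm applied at {depth} cm; "
            "pass allow_depth_mismatch=True to override")


@dataclass(frozen=True)
class GafCalib:
    """Film calibration: dose(x)=a+b*x/ln(x); u%(D)=ua+ub*exp(-D/uc)."""

    a: float
    b: float
    unc_a: float | None = None
    unc_b: float | None = None
    unc_c: float | None = None
    depth_cm: float | None = None
    dose_range_mgy: tuple = (1.0, 10.0)
    residuals: tuple = ()


@dataclass(frozen=True)
class TLDCalib:
    k_calib: float                      # mGy/nC
    sensitivity: dict = field(default_factory=dict)   # chip id -> S_i
    depth_cm: float | None = None

    def __post_init__(self):
        if self.k_calib <= 0:
            raise ValueError("K_calib must be positive")
        if any(s <= 0 for s in self.sensitivity.values()):
            raise ValueError("sensitivities must be positive")


@dataclass(frozen=True)
class MOSFETCalib:
    cf: float                           # mV/mGy
    depth_cm: float | None = None

    def __post_init__(self):
        if self.cf <= 0:
            raise ValueError("calibration factor must be positive")


@dataclass(frozen=True)
class UncertaintyComponent:
    """Relative uncertainty component (percent).

    Type A: ``value`` is the standard uncertainty.  Type B rectangular:
    ``value`` is the half-width, converted to standard form by /sqrt(3).
    """

    value: float
    kind: str = "A"                     # "A" or "B_rectangular"
    label: str = ""

    def standard(self) -> float:
        if self.value < 0:
            raise ValueError("uncertainty must be nonnegative")
        if self.kind == "A":
            return self.value
        if self.kind == "B_rectangular":
            return self.value / math.sqrt(3.0)
        raise ValueError(f"unknown uncertainty type {self.kind!r}")


# ---------------------------------------------------------------------------
# GafChromic film

def _gaf_basis(x):
    x = np.asarray(x, float)
    if np.any(x <= 0) or np.any(x == 1.0):
        raise ValueError("netDeltaR must be in (0,1) excluding 1 (ln x = 0)")
    return x / np.log(x)


def fit_gaf_calibration(net_dr, kerma_mgy, depth_cm=None,
                        unc_params=None) -> GafCalib:
    """Least-squares fit of dose = a + b*x/ln(x) to calibration pairs.

    The model is linear in (a, b); a rank warning is emitted for a
    degenerate design (e.g. repeated x with conflicting doses resolve in
    the least-squares sense).
    """
    x = np.asarray(net_dr, float)
    y = np.asarray(kerma_mgy, float)
    if x.size < 3:
        raise ValueError("need at least 3 calibration pairs")
    basis = _gaf_basis(x)
    design = np.column_stack([np.ones_like(basis), basis])
    coef, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    if rank < 2 or np.unique(x).size < 2:
        warnings.warn("rank-deficient film calibration design", RuntimeWarning)
    resid = y - design @ coef
    unc = unc_params or {}
    return GafCalib(a=float(coef[0]), b=float(coef[1]),
                    unc_a=unc.get("a"), unc_b=unc.get("b"), unc_c=unc.get("c"),
                    depth_cm=depth_cm, residuals=tuple(resid))


def gaf_dose(net_dr, calib: GafCalib, depth_cm=None,
             allow_depth_mismatch=False):
    """Dose (mGy) from net reflectance change via the film calibration."""
    _check_depth(calib.depth_cm, depth_cm, allow_depth_mismatch)
    out = calib.a + calib.b * _gaf_basis(net_dr)
    return float(out) if np.ndim(net_dr) == 0 else out


def gaf_uncertainty(dose_mgy, calib: GafCalib):
    """Combined relative uncertainty (percent) of a film dose value."""
    if calib.unc_a is None:
        raise ValueError("calibration has no uncertainty model")
    d = np.asarray(dose_mgy, float)
    out = calib.unc_a + calib.unc_b * np.exp(-d / calib.unc_c)
    return float(out) if np.ndim(dose_mgy) == 0 else out


# ---------------------------------------------------------------------------
# TLD and MOSFET

def tld_dose(q_nc, calib: TLDCalib, chip=None, depth_cm=None,
             allow_depth_mismatch=False):
    """TLD dose D = Q * K_calib / S.

    ``q_nc`` may be a scalar reading or a sequence of per-chip readings
    (one measurement position uses the mean of its chips).  ``chip`` gives
    the chip id(s) for sensitivity lookup; unknown chips default to S=1.
    """
    _check_depth(calib.depth_cm, depth_cm, allow_depth_mismatch)
    q = np.atleast_1d(np.asarray(q_nc, float))
    if np.any(q < 0):
        raise ValueError("negative TLD reading")
    chips = [chip] if np.ndim(chip) == 0 else list(chip or [None] * q.size)
    if len(chips) == 1 and q.size > 1:
        chips = chips * q.size
    s = np.array([calib.sensitivity.get(c, 1.0) for c in chips])
    if np.any(s == 0):
        raise ValueError("zero sensitivity factor")
    doses = q * calib.k_calib / s
    return float(doses.mean())


def mosfet_dose(delta_v_mv, calib: MOSFETCalib, depth_cm=None,
                allow_depth_mismatch=False):
    """MOSFET dose: mean of deltaV/CF over the (typically 3) exposures."""
    _check_depth(calib.depth_cm, depth_cm, allow_depth_mismatch)
    dv = np.atleast_1d(np.asarray(delta_v_mv, float))
    if np.any(dv < 0):
        warnings.warn("negative MOSFET signal (voltage inversion?)",
                      RuntimeWarning)
    return float(np.mean(dv / calib.cf))


def combine_uncertainty(components) -> float:
    """Quadrature combination of relative components -> k=1 combined %, with
    rectangular Type B components converted by half-width/sqrt(3) first."""
    comps = [c if isinstance(c, UncertaintyComponent)
             else UncertaintyComponent(float(c)) for c in components]
    if not comps:
        raise ValueError("need at least one component")
    return math.sqrt(sum(c.standard() ** 2 for c in comps))


# ---------------------------------------------------------------------------
# synthetic reading generator (for end-to-end tests)

def _gaf_invert(dose, calib: GafCalib):
    """Solve a + b*x/ln(x) = dose for x in (0,1)."""
    from scipy.optimize import brentq
    lo, hi = 1e-6, 1.0 - 1e-9

    def f(x):
        return calib.a + calib.b * (x / math.log(x)) - dose
    if f(lo) * f(hi) > 0:
        raise ValueError(f"dose {dose} mGy outside invertible film range")
    return brentq(f, lo, hi, xtol=1e-12)


def synth_readings(true_doses, calib, noise_percent: float, seed: int,
                   n_repeats: int = 1):
    """Emulated dosimeter readings for known true doses.

    Readings are obtained by inverting the calibration model and adding
    Gaussian noise of the given relative scale; reconstructing doses from
    them with the same calibration is unbiased.  Film calibrations yield
    netDeltaR values, TLD calibrations nC readings (S=1 chips), MOSFET
    calibrations mV signals.  Doses outside the film calibration range
    trigger a warning.
    """
    rng = np.random.default_rng(seed)
    doses = np.atleast_1d(np.asarray(true_doses, float))
    if isinstance(calib, GafCalib):
        lo, hi = calib.dose_range_mgy
        if np.any((doses < lo) | (doses > hi)):
            warnings.warn("dose outside film calibration range", RuntimeWarning)
        clean = np.array([_gaf_invert(d, calib) for d in doses])
    elif isinstance(calib, TLDCalib):
        clean = doses / calib.k_calib
    elif isinstance(calib, MOSFETCalib):
        clean = doses * calib.cf
    else:
        raise TypeError(f"unsupported calibration {type(calib).__name__}")
    shape = (n_repeats, clean.size) if n_repeats > 1 else clean.shape
    noisy = clean * (1.0 + noise_percent / 100.0
                     * rng.standard_normal(shape))
    return noisy
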