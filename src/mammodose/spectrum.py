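"""Polyenergetic mammographic x-ray spectrum modelling.

A spectrum is stored as a binned differential *energy* fluence psi_E
(energy per unit area per unit energy, relative units) on an ascending
energy-bin grid.  The module provides a Kramers-law bremsstrahlung
generator with inherent beryllium filtration, Beer-Lambert filtration,
analytic air kerma, first half-value-layer (HVL) computation, filter
tuning against a measured aluminium attenuation curve or a target HVL,
and spectrum-averaged mass energy-absorption ratios used to convert dose
scored in a dosimeter material to dose in air.
"""
from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
from scipy.optimize import bisect, minimize_scalar

from .materials import Material, get_material, mu_over_rho, muen_over_rho

__all__ = [
    "Spectrum", "AttenuationCurve", "generate_bremsstrahlung", "attenuate",
    "air_kerma", "first_hvl", "tune_filter", "spectrum_avg_muen_ratio",
    "read_spectrum", "write_spectrum", "KEV_PER_G_TO_MGY",
]

# 1 keV/g deposited corresponds to this many mGy
KEV_PER_G_TO_MGY = 1.602176634e-10

_E_MIN = 1.0  # keV; lower bound of the bundled cross-section tables


class DegenerateSpectrumError(ValueError):
    pass


@dataclass(frozen=True)
class Spectrum:
    """Binned differential energy fluence."""

    bin_edges: np.ndarray     # keV, ascending, length n+1
    psi_E: np.ndarray         # differential energy fluence per keV, length n
    kvp: float                # tube potential, keV

    def __post_init__(self):
        edges = np.asarray(self.bin_edges, float)
        psi = np.asarray(self.psi_E, float)
        if edges.ndim != 1 or psi.shape != (edges.size - 1,):
            raise ValueError("bin_edges must have len(psi_E)+1 entries")
        if not np.all(np.diff(edges) > 0):
            raise ValueError("bin edges must ascend")
        if np.any(psi < 0):
            raise ValueError("psi_E must be nonnegative")
        object.__setattr__(self, "bin_edges", edges)
        object.__setattr__(self, "psi_E", psi)

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def widths(self) -> np.ndarray:
        return np.diff(self.bin_edges)

    @property
    def energy_fluence(self) -> float:
        """Integral energy fluence psi (relative units)."""
        return float(np.sum(self.psi_E * self.widths))

    @property
    def photon_fluence_per_bin(self) -> np.ndarray:
        return self.psi_E * self.widths / self.centers

    @property
    def photon_fluence(self) -> float:
        return float(np.sum(self.photon_fluence_per_bin))

    def mean_energy(self) -> float:
        """Photon-fluence-weighted mean energy (keV)."""
        phi = self.photon_fluence_per_bin
        tot = phi.sum()
        if tot <= 0:
            raise DegenerateSpectrumError("empty spectrum")
        return float(np.sum(phi * self.centers) / tot)

    def scaled(self, factor: float) -> "Spectrum":
        return Spectrum(self.bin_edges, self.psi_E * factor, self.kvp)


def generate_bremsstrahlung(kvp: float, bin_width: float = 0.25,
                            inherent_be_mm: float = 0.69,
                            anode_self_filtration_um_w: float = 5.0) -> Spectrum:
    """Semi-analytic tungsten-anode tube spectrum.

    The unfiltered differential photon fluence follows the Kramers shape
    (kVp - E)/E, i.e. a linear differential energy fluence (kVp - E),
    binned from 1 keV to the tube potential, then filtered by the inherent
    beryllium window and by an effective tungsten anode self-filtration
    path (the pure Kramers shape is well known to be too soft because it
    neglects absorption of the beam inside the target; a few micrometres
    of W-equivalent path restores a realistic mammographic beam quality).
    The result is normalized to unit integral photon fluence.
    """
    if kvp <= 0:
        raise ValueError("kVp must be positive")
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    edges = np.arange(_E_MIN, kvp + bin_width * 0.5, bin_width)
    if edges[-1] < kvp:
        edges = np.append(edges, kvp)
    centers = 0.5 * (edges[:-1] + edges[1:])
    psi = np.maximum(kvp - centers, 0.0)
    s = Spectrum(edges, psi, kvp)
    if anode_self_filtration_um_w:
        s = attenuate(s, get_material("tungsten"),
                      anode_self_filtration_um_w / 1000.0)
    if inherent_be_mm:
        s = attenuate(s, get_material("beryllium"), inherent_be_mm)
    return s.scaled(1.0 / s.photon_fluence)


def attenuate(spectrum: Spectrum, material: Material,
              thickness_mm: float) -> Spectrum:
    """Beer-Lambert filtration through ``thickness_mm`` of ``material``."""
    if thickness_mm < 0:
        raise ValueError("thickness must be nonnegative")
    if thickness_mm == 0:
        return spectrum
    mu = mu_over_rho(material, spectrum.centers) * material.density  # 1/cm
    trans = np.exp(-mu * thickness_mm / 10.0)
    return Spectrum(spectrum.bin_edges, spectrum.psi_E * trans, spectrum.kvp)


def air_kerma(spectrum: Spectrum, fluence_scale: float = 1.0) -> float:
    """Air kerma of the spectrum in mGy (for the given fluence scale).

    K = sum over bins of Phi(E) * E * (muen/rho)_air(E).
    """
    if spectrum.psi_E.size == 0:
        raise DegenerateSpectrumError("empty spectrum")
    air = get_material("air")
    centers = spectrum.centers
    muen = muen_over_rho(air, centers)
    k = np.sum(spectrum.photon_fluence_per_bin * centers * muen)
    return float(k * fluence_scale * KEV_PER_G_TO_MGY)


def first_hvl(spectrum: Spectrum, absorber: Material | None = None,
              bracket_mm=(0.01, 5.0), tol_mm: float = 1e-4) -> float:
    """First half-value layer in ``absorber`` (default aluminium), in mm.

    Found by bisection on the air-kerma transmission curve, which is
    strictly monotone in absorber thickness.
    """
    absorber = absorber or get_material("aluminum")
    k0 = air_kerma(spectrum)
    if k0 <= 0:
        raise DegenerateSpectrumError("spectrum has zero air kerma")

    def f(t):
        return air_kerma(attenuate(spectrum, absorber, t)) / k0 - 0.5

    lo, hi = bracket_mm
    if f(lo) < 0 or f(hi) > 0:
        raise DegenerateSpectrumError(
            f"HVL not bracketed in [{lo}, {hi}] mm")
    return float(bisect(f, lo, hi, xtol=tol_mm))


@dataclass(frozen=True)
class AttenuationCurve:
    """Measured air-kerma transmission versus aluminium thickness."""

    thickness_mm: np.ndarray
    transmission: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.thickness_mm, float)
        tr = np.asarray(self.transmission, float)
        if t.shape != tr.shape or t.ndim != 1 or t.size == 0:
            raise ValueError("thickness and transmission must be 1D, equal length")
        if np.any(t < 0) or not np.all(np.diff(t) > 0):
            raise ValueError("thicknesses must be nonnegative and ascending")
        if np.any(tr <= 0) or np.any(tr > 1) or np.any(np.diff(tr) > 0):
            raise ValueError("transmission must be in (0,1] and nonincreasing")
        object.__setattr__(self, "thickness_mm", t)
        object.__setattr__(self, "transmission", tr)

    @classmethod
    def from_csv(cls, path) -> "AttenuationCurve":
        arr = np.loadtxt(path, delimiter=",", comments="#")
        arr = np.atleast_2d(arr)
        return cls(arr[:, 0], arr[:, 1])

    def to_csv(self, path) -> None:
        np.savetxt(path, np.column_stack([self.thickness_mm, self.transmission]),
                   delimiter=",", header="thickness_mm,transmission")


class TuningError(RuntimeError):
    pass


def _predicted_curve(spectrum: Spectrum, thicknesses, absorber) -> np.ndarray:
    k0 = air_kerma(spectrum)
    return np.array([air_kerma(attenuate(spectrum, absorber, t)) / k0
                     for t in thicknesses])


def tune_filter(spectrum: Spectrum, filter_material: Material,
                attenuation_curve: AttenuationCurve | None = None,
                target_hvl_mm: float | None = None,
                absorber: Material | None = None,
                bounds_mm=(0.005, 0.15)) -> float:
    """Find the filter thickness (mm) matching a beam-quality target.

    With ``attenuation_curve``: minimizes the sum of squared transmission
    residuals over the measured aluminium layers.  With ``target_hvl_mm``:
    solves |HVL(t) - target| = 0 by bisection (transmission hardening is
    monotone in filter thickness).
    """
    absorber = absorber or get_material("aluminum")
    if (attenuation_curve is None) == (target_hvl_mm is None):
        raise ValueError("provide exactly one of attenuation_curve/target_hvl_mm")

    if target_hvl_mm is not None:
        def g(t):
            return first_hvl(attenuate(spectrum, filter_material, t),
                             absorber) - target_hvl_mm
        lo, hi = bounds_mm
        glo, ghi = g(lo), g(hi)
        if glo * ghi > 0:
            raise TuningError(
                f"target HVL {target_hvl_mm} mm not reachable for filter "
                f"thickness in [{lo}, {hi}] mm (residuals {glo:.4g}, {ghi:.4g})")
        return float(bisect(g, lo, hi, xtol=1e-6))

    curve = attenuation_curve
    informative = curve.thickness_mm > 0
    if not np.any(informative):
        raise TuningError("attenuation curve has no nonzero-thickness point")
    if spectrum.psi_E[spectrum.psi_E > 0].size == 1:
        # a single occupied bin transmits exp(-mu t) regardless of filter
        raise TuningError("degenerate (monoenergetic) spectrum: objective "
                          "is flat in filter thickness")

    def sse(t):
        filtered = attenuate(spectrum, filter_material, t)
        pred = _predicted_curve(filtered, curve.thickness_mm, absorber)
        return float(np.sum((pred - curve.transmission) ** 2))

    res = minimize_scalar(sse, bounds=bounds_mm, method="bounded",
                          options={"xatol": 1e-7})
    if not res.success:
        raise TuningError(f"filter tuning failed: {res.message}; "
                          f"residual {res.fun:.4g}")
    return float(res.x)


def spectrum_avg_muen_ratio(spectrum: Spectrum, mat_num: Material,
                            mat_den: Material) -> float:
    """Ratio of psi_E-weighted mean mass energy-absorption coefficients.

    (1/psi) int (muen/rho)_num psi_E dE over the same average for the
    denominator material.  Supply the depth-hardened spectrum to account
    for beam hardening at the scoring depth.
    """
    w = spectrum.psi_E * spectrum.widths
    if w.sum() <= 0:
        raise DegenerateSpectrumError("zero integral energy fluence")
    centers = spectrum.centers
    num = np.sum(w * muen_over_rho(mat_num, centers))
    den = np.sum(w * muen_over_rho(mat_den, centers))
    return float(num / den)


# ---------------------------------------------------------------------------
# TSV interchange

def write_spectrum(spectrum: Spectrum, path) -> None:
    """Write 'E_keV<TAB>relative fluence' rows (photon fluence per bin)."""
    with open(path, "w") as fh:
        fh.write(f"# kVp_keV = {spectrum.kvp}\n")
        fh.write(f"# bin_width_keV = {spectrum.widths[0]:.6g}\n")
        fh.write("# E_keV\trelative_photon_fluence\n")
        for e, phi in zip(spectrum.centers, spectrum.photon_fluence_per_bin):
            fh.write(f"{e:.6g}\t{phi:.8g}\n")


def read_spectrum(path) -> Spectrum:
    """Read a two-column (bin center, relative photon fluence) TSV."""
    kvp = None
    rows = []
    text = path.read_text() if hasattr(path, "read_text") else open(path).read()
    for line in io.StringIO(text):
        if line.startswith("#"):
            if "kVp_keV" in line:
                kvp = float(line.split("=")[1])
            continue
        if line.strip():
            e, phi = line.split()
            rows.append((float(e), float(phi)))
    if not rows:
        raise ValueError(f"no spectrum rows in {path}")
    centers = np.array([r[0] for r in rows])
    phi = np.array([r[1] for r in rows])
    width = np.median(np.diff(centers)) if centers.size > 1 else 1.0
    edges = np.concatenate([centers - width / 2, [centers[-1] + width / 2]])
    psi = phi * centers / np.diff(edges)
    return Spectrum(edges, psi, kvp if kvp is not None else float(edges[-1]))
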