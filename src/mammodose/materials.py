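"""Elemental photon cross sections and material/mixture construction.

Elemental mass attenuation data (total, photoelectric, coherent, incoherent
and mass energy-absorption coefficients, cm^2/g, 1-50 keV) are bundled as
packaged TSV tables.  Materials are defined by a density and elemental mass
fractions; mixture coefficients follow the standard mass-weighted mixture
rule with log-log interpolation between tabulated energies.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources

import numpy as np
import yaml

__all__ = [
    "ElementRecord", "Material", "load_element", "make_material",
    "mix_by_mass", "mu_over_rho", "muen_over_rho", "partial_mu_over_rho",
    "get_material", "list_materials", "ATOMIC_WEIGHTS",
]

ATOMIC_WEIGHTS = {
    "H": 1.008, "Li": 6.94, "Be": 9.0122, "C": 12.011, "N": 14.007,
    "O": 15.999, "F": 18.998, "Na": 22.990, "Mg": 24.305, "Al": 26.982,
    "P": 30.974, "S": 32.06, "Cl": 35.45, "Ar": 39.948, "K": 39.098,
    "Ca": 40.078, "Cu": 63.546, "Rh": 102.906, "W": 183.84,
}

_COMPOSITION_TOL = 1e-6


class InvalidCompositionError(ValueError):
    """Mass fractions do not form a valid composition."""


class EnergyRangeError(ValueError):
    """Requested photon energy lies outside the tabulated grid."""


@dataclass(frozen=True)
class ElementRecord:
    """Tabulated photon interaction coefficients for one element."""

    Z: int
    symbol: str
    A: float
    energy_grid: np.ndarray        # keV, ascending
    mu_rho_total: np.ndarray       # cm^2/g
    mu_rho_pe: np.ndarray
    mu_rho_coh: np.ndarray
    mu_rho_incoh: np.ndarray
    muen_rho: np.ndarray

    def __post_init__(self):
        g = self.energy_grid
        if not np.all(np.diff(g) > 0):
            raise ValueError(f"{self.symbol}: energy grid not ascending")
        if g[0] > 1.0 or g[-1] < 40.0:
            raise ValueError(f"{self.symbol}: grid does not cover 1-40 keV")


@lru_cache(maxsize=None)
def load_element(symbol: str) -> ElementRecord:
    """Load the packaged table for one element (cached)."""
    if symbol not in ATOMIC_WEIGHTS:
        raise KeyError(f"unknown element {symbol!r}")
    ref = resources.files("mammodose").joinpath(f"data/elements/{symbol}.tsv")
    rows = []
    z = None
    for line in ref.read_text().splitlines():
        if line.startswith("#"):
            m = re.search(r"Z=(\d+)", line)
            if m:
                z = int(m.group(1))
            continue
        if line.strip():
            rows.append([float(x) for x in line.split("\t")])
    arr = np.array(rows)
    return ElementRecord(
        Z=z, symbol=symbol, A=ATOMIC_WEIGHTS[symbol],
        energy_grid=arr[:, 0], mu_rho_total=arr[:, 1], mu_rho_pe=arr[:, 2],
        mu_rho_coh=arr[:, 3], mu_rho_incoh=arr[:, 4], muen_rho=arr[:, 5],
    )


@dataclass(frozen=True)
class Material:
    """A homogeneous material: density and elemental mass fractions."""

    name: str
    density: float                      # g/cm^3
    mass_fractions: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.density <= 0:
            raise InvalidCompositionError(f"{self.name}: density must be > 0")
        s = sum(self.mass_fractions.values())
        if abs(s - 1.0) > 1e-9:
            raise InvalidCompositionError(
                f"{self.name}: mass fractions sum to {s}, expected 1")

    def with_density(self, density: float) -> "Material":
        return Material(self.name, density, dict(self.mass_fractions))


_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


def _expand_formula(formula: str) -> dict:
    """Elemental mass fractions of a simple chemical formula (e.g. LiF)."""
    parts = [(el, int(n) if n else 1)
             for el, n in _FORMULA_RE.findall(formula) if el]
    if not parts or "".join(f"{el}{'' if n == 1 else n}" for el, n in parts) != formula:
        raise InvalidCompositionError(f"cannot parse formula {formula!r}")
    masses = {}
    for el, n in parts:
        if el not in ATOMIC_WEIGHTS:
            raise InvalidCompositionError(f"unknown element {el!r} in {formula!r}")
        masses[el] = masses.get(el, 0.0) + n * ATOMIC_WEIGHTS[el]
    total = sum(masses.values())
    return {el: m / total for el, m in masses.items()}


def make_material(name: str, mass_fractions: dict, density: float) -> Material:
    """Build a Material, expanding compound entries by stoichiometric mass.

    ``mass_fractions`` maps element symbols or simple formulas (``"LiF"``)
    to mass fractions; fractions must be nonnegative and sum to 1 within
    1e-6 (they are renormalized to machine precision).
    """
    if any(v < 0 for v in mass_fractions.values()):
        raise InvalidCompositionError(f"{name}: negative mass fraction")
    s = float(sum(mass_fractions.values()))
    if abs(s - 1.0) > _COMPOSITION_TOL:
        raise InvalidCompositionError(
            f"{name}: mass fractions sum to {s:.6g}, expected 1")
    out: dict = {}
    for key, frac in mass_fractions.items():
        if frac == 0:
            continue
        sub = {key: 1.0} if key in ATOMIC_WEIGHTS else _expand_formula(key)
        for el, w in sub.items():
            out[el] = out.get(el, 0.0) + frac * w / s
    return Material(name, float(density), out)


def mix_by_mass(materials, weights, name: str | None = None) -> Material:
    """Mass-weighted mixture of materials.

    Elemental fractions are mass-weighted sums and the mixture density is
    the harmonic (volume-conserving) mean ``1 / sum(w_i / rho_i)``.
    """
    materials = list(materials)
    weights = [float(w) for w in weights]
    if not materials or len(materials) != len(weights):
        raise InvalidCompositionError("need equal, nonempty materials/weights")
    if any(w < 0 for w in weights):
        raise InvalidCompositionError("negative mixture weight")
    s = sum(weights)
    if abs(s - 1.0) > _COMPOSITION_TOL:
        raise InvalidCompositionError(f"mixture weights sum to {s:.6g}")
    weights = [w / s for w in weights]
    fractions: dict = {}
    inv_density = 0.0
    for m, w in zip(materials, weights):
        inv_density += w / m.density
        for el, f in m.mass_fractions.items():
            fractions[el] = fractions.get(el, 0.0) + w * f
    name = name or "+".join(f"{w:.3g}*{m.name}" for m, w in zip(materials, weights))
    return Material(name, 1.0 / inv_density, fractions)


# ---------------------------------------------------------------------------
# coefficient lookup

_FIELDS = {
    "total": "mu_rho_total", "pe": "mu_rho_pe", "coh": "mu_rho_coh",
    "incoh": "mu_rho_incoh", "muen": "muen_rho",
}


def _interp_element(rec: ElementRecord, energy_kev, fieldname: str):
    e = np.asarray(energy_kev, float)
    g = rec.energy_grid
    if np.any(e < g[0]) or np.any(e > g[-1]):
        raise EnergyRangeError(
            f"{rec.symbol}: energy outside tabulated range "
            f"[{g[0]:.3g}, {g[-1]:.3g}] keV")
    v = getattr(rec, fieldname)
    out = np.exp(np.interp(np.log(e), np.log(g), np.log(v)))
    return out if np.ndim(energy_kev) else float(out)


def partial_mu_over_rho(material: Material, energy_kev, kind: str):
    """Mass coefficient of one interaction channel (cm^2/g).

    ``kind`` is one of ``total``, ``pe``, ``coh``, ``incoh``, ``muen``.
    Mixture rule: sum_i w_i (mu/rho)_i(E) with log-log interpolation per
    element, exact at element grid points.
    """
    fieldname = _FIELDS[kind]
    out = None
    for el, w in material.mass_fractions.items():
        term = w * np.asarray(_interp_element(load_element(el), energy_kev,
                                              fieldname))
        out = term if out is None else out + term
    return out if np.ndim(energy_kev) else float(out)


def mu_over_rho(material: Material, energy_kev):
    """Total mass attenuation coefficient (cm^2/g)."""
    return partial_mu_over_rho(material, energy_kev, "total")


def muen_over_rho(material: Material, energy_kev):
    """Mass energy-absorption coefficient (cm^2/g)."""
    return partial_mu_over_rho(material, energy_kev, "muen")


# ---------------------------------------------------------------------------
# built-in registry

@lru_cache(maxsize=1)
def _registry() -> dict:
    ref = resources.files("mammodose").joinpath("data/materials.yaml")
    raw = yaml.safe_load(ref.read_text())
    reg = {}
    for name, spec in raw.items():
        reg[name] = make_material(name, spec["mass_fractions"],
                                  spec["density"])
    # CIRS-style 50% glandular / 50% adipose phantom material
    reg["breast_50_50"] = mix_by_mass(
        [reg["glandular"], reg["adipose"]], [0.5, 0.5], name="breast_50_50")
    return reg


def get_material(name: str) -> Material:
    """Look up a built-in material by name."""
    try:
        return _registry()[name]
    except KeyError:
        raise KeyError(
            f"unknown material {name!r}; available: {sorted(_registry())}")


def list_materials():
    return sorted(_registry())
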