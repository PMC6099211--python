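"""Voxelized compressed-breast phantoms and dosimeter placement.

Coordinate convention (right-handed, mm): origin at the chest-wall edge on
the detector midline; x lateral, y chest wall -> nipple, z upward from the
support-table top.  Phantom grids are stored with 0-based indices and
half-open voxel extents; label 0 is always air.

Two phantoms are provided: a homogeneous semicylindrical slab phantom
(50% glandular / 50% adipose by mass, CIRS-style) and a synthetic
anthropomorphic stand-in with a 1.5 mm skin shell, adipose background and
centrally concentrated glandular blobs matched to a target glandularity by
mass (default 10.9%).
"""
from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .materials import Material, get_material, mix_by_mass

__all__ = [
    "VoxelPhantom", "SensitiveVolume", "build_homogeneous",
    "build_synthetic_breast", "glandular_mass_fraction", "homogenize",
    "tld_positions", "read_phantom", "write_phantom", "DEFAULT_LAYOUT",
    "CHIP_DIMS_MM",
]

AIR_LABEL = 0
CHIP_DIMS_MM = (3.2, 3.2, 0.38)

#: Default 30-position dosimeter layout: 5 rows (distance from chest wall)
#: by 6 lateral columns.  The 30 positions of the reference experiment are
#: published only graphically, so the layout is configuration-driven with
#: this documented default.
DEFAULT_LAYOUT = {
    "rows_y_mm": (20.0, 45.0, 70.0, 95.0, 120.0),
    "cols_x_mm": (-40.0, -24.0, -8.0, 8.0, 24.0, 40.0),
}


class PhantomFormatError(ValueError):
    pass


@dataclass
class VoxelPhantom:
    """Labelled voxel grid plus label -> material map."""

    labels: np.ndarray                  # uint8, shape (nx, ny, nz)
    voxel_mm: float
    label_map: dict                     # label -> Material
    origin_mm: tuple = (0.0, 0.0, 0.0)  # grid corner in phantom frame
    glandular_share: dict = field(default_factory=dict)  # label -> mass share

    def __post_init__(self):
        if self.voxel_mm <= 0:
            raise ValueError("voxel size must be positive")
        if self.labels.size == 0:
            raise ValueError("empty label grid")
        present = set(np.unique(self.labels).tolist())
        missing = present - set(self.label_map) - {AIR_LABEL}
        if missing:
            raise PhantomFormatError(f"labels {sorted(missing)} not in label_map")
        for lab in self.label_map:
            self.glandular_share.setdefault(
                lab, 1.0 if self.label_map[lab].name == "glandular" else 0.0)

    @property
    def shape(self):
        return self.labels.shape

    @property
    def thickness_cm(self) -> float:
        return self.labels.shape[2] * self.voxel_mm / 10.0

    @property
    def extent_mm(self):
        o = np.asarray(self.origin_mm, float)
        return o, o + np.array(self.labels.shape) * self.voxel_mm

    def voxel_volume_cm3(self) -> float:
        return (self.voxel_mm / 10.0) ** 3

    def density_grid(self) -> np.ndarray:
        """Per-voxel density (g/cm^3); air voxels get air density."""
        dens = np.zeros(256)
        dens[AIR_LABEL] = get_material("air").density
        for lab, mat in self.label_map.items():
            dens[lab] = mat.density
        return dens[self.labels]

    def tissue_mask(self) -> np.ndarray:
        return self.labels != AIR_LABEL

    def label_at(self, point_mm) -> int:
        idx = np.floor((np.asarray(point_mm, float) - self.origin_mm)
                       / self.voxel_mm).astype(int)
        if np.any(idx < 0) or np.any(idx >= self.labels.shape):
            return AIR_LABEL
        return int(self.labels[tuple(idx)])


@dataclass(frozen=True)
class SensitiveVolume:
    """A TLD-chip-sized scoring box (3.2 x 3.2 x 0.38 mm^3 of TLD material)."""

    center_mm: tuple                    # (x, y, z) in phantom frame
    dims_mm: tuple = CHIP_DIMS_MM
    material_name: str = "tld"

    @property
    def bounds_mm(self):
        c = np.asarray(self.center_mm, float)
        h = np.asarray(self.dims_mm, float) / 2.0
        return c - h, c + h

    def volume_cm3(self) -> float:
        d = np.asarray(self.dims_mm, float)
        return float(np.prod(d)) / 1000.0


def _semicircle_grid(radius_mm, thickness_cm, voxel_mm):
    nx = int(np.ceil(2 * radius_mm / voxel_mm))
    ny = int(np.ceil(radius_mm / voxel_mm))
    nz = int(np.ceil(thickness_cm * 10.0 / voxel_mm))
    origin = (-nx * voxel_mm / 2.0, 0.0, 0.0)
    ix, iy = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    x = origin[0] + (ix + 0.5) * voxel_mm
    y = (iy + 0.5) * voxel_mm
    r2 = x ** 2 + y ** 2
    return nx, ny, nz, origin, x, y, r2


def build_homogeneous(radius_mm: float = 100.0, thickness_cm: float = 5.0,
                      voxel_mm: float = 0.273,
                      material: Material | None = None) -> VoxelPhantom:
    """Semicylindrical homogeneous slab phantom, flat face at the chest wall.

    All in-phantom voxels share one label (default material: the 50/50
    glandular/adipose mixture); everything else is air.
    """
    if radius_mm <= 0 or thickness_cm <= 0:
        raise ValueError("radius and thickness must be positive")
    if voxel_mm > min(2 * radius_mm, thickness_cm * 10.0):
        raise ValueError("voxel larger than phantom")
    material = material or get_material("breast_50_50")
    nx, ny, nz, origin, x, y, r2 = _semicircle_grid(radius_mm, thickness_cm,
                                                    voxel_mm)
    inside = r2 <= radius_mm ** 2
    labels = np.zeros((nx, ny, nz), dtype=np.uint8)
    labels[inside, :] = 1
    share = 0.0
    if material.name == "breast_50_50":
        share = 0.5
    elif material.name == "glandular":
        share = 1.0
    return VoxelPhantom(labels=labels, voxel_mm=voxel_mm,
                        label_map={1: material}, origin_mm=origin,
                        glandular_share={1: share})


ADIPOSE_LABEL, GLANDULAR_LABEL, SKIN_LABEL = 1, 2, 3


def build_synthetic_breast(seed: int, thickness_cm: float = 4.5,
                           target_glandularity: float = 0.109,
                           radius_mm: float = 80.0, voxel_mm: float = 1.0,
                           blob_params: dict | None = None) -> VoxelPhantom:
    """Synthetic trinary (skin/adipose/glandular) compressed-breast phantom.

    A semicylindrical outline with a 1.5 mm skin shell and adipose
    background; glandular tissue is laid down as smoothed random blobs
    biased toward the phantom center (both laterally and in depth), with
    the blob threshold solved so the achieved glandular *mass* fraction
    matches ``target_glandularity`` within +/-0.005.  Reproducible by seed.
    """
    if not 0.0 <= target_glandularity < 1.0:
        raise ValueError("target glandularity must be in [0, 1)")
    p = {"correlation_mm": 3.0, "central_bias": 1.2, "skin_mm": 1.5,
         "z_sigma_frac": 0.25}
    if blob_params:
        p.update(blob_params)
    nx, ny, nz, origin, x, y, r2 = _semicircle_grid(radius_mm, thickness_cm,
                                                    voxel_mm)
    z = (np.arange(nz) + 0.5) * voxel_mm
    inside = r2 <= radius_mm ** 2
    labels = np.zeros((nx, ny, nz), dtype=np.uint8)
    labels[inside, :] = ADIPOSE_LABEL

    # skin shell: lateral rim plus top and bottom faces (not the chest wall)
    rim = inside & (r2 > (radius_mm - p["skin_mm"]) ** 2)
    labels[rim, :] = SKIN_LABEL
    n_skin_z = max(1, int(round(p["skin_mm"] / voxel_mm)))
    labels[inside, :n_skin_z] = SKIN_LABEL
    labels[inside, nz - n_skin_z:] = SKIN_LABEL

    label_map = {ADIPOSE_LABEL: get_material("adipose"),
                 GLANDULAR_LABEL: get_material("glandular"),
                 SKIN_LABEL: get_material("skin")}

    if target_glandularity == 0.0:
        return VoxelPhantom(labels=labels, voxel_mm=voxel_mm,
                            label_map=label_map, origin_mm=origin)

    rng = np.random.default_rng(seed)
    noise = rng.standard_normal((nx, ny, nz))
    sigma = p["correlation_mm"] / voxel_mm
    blobs = gaussian_filter(noise, sigma)
    blobs /= max(blobs.std(), 1e-12)
    # additive central biases: glandular tissue favors mid-depth at every
    # lateral position, and the middle of the footprint
    env_xy = np.exp(-((x ** 2 + (y - radius_mm * 0.45) ** 2)
                      / (2 * (radius_mm * 0.45) ** 2)))
    sigma_z = p["z_sigma_frac"] * thickness_cm * 10.0
    env_z = np.exp(-((z - z.mean()) ** 2) / (2 * sigma_z ** 2))
    score = blobs + p["central_bias"] * env_z[None, None, :] \
        + 0.5 * p["central_bias"] * env_xy[:, :, None]

    interior = labels == ADIPOSE_LABEL
    rho_a = label_map[ADIPOSE_LABEL].density
    rho_g = label_map[GLANDULAR_LABEL].density
    m_skin = np.count_nonzero(labels == SKIN_LABEL) * label_map[SKIN_LABEL].density
    n_int = np.count_nonzero(interior)
    sc = score[interior]

    def frac_for(tau):
        n_g = np.count_nonzero(sc > tau)
        m_g = n_g * rho_g
        m_a = (n_int - n_g) * rho_a
        return m_g / (m_g + m_a + m_skin)

    lo, hi = sc.min() - 1.0, sc.max() + 1.0
    if frac_for(lo) < target_glandularity:
        raise ValueError("target glandularity unreachable with these blob_params")
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if frac_for(mid) > target_glandularity:
            lo = mid
        else:
            hi = mid
    tau = 0.5 * (lo + hi)
    gl = interior & (score > tau)
    labels[gl] = GLANDULAR_LABEL

    ph = VoxelPhantom(labels=labels, voxel_mm=voxel_mm, label_map=label_map,
                      origin_mm=origin)
    achieved = glandular_mass_fraction(ph)
    if abs(achieved - target_glandularity) > 0.005:
        raise ValueError(
            f"achieved glandularity {achieved:.4f} misses target "
            f"{target_glandularity:.4f} by more than 0.005")
    return ph


def glandular_mass_fraction(phantom: VoxelPhantom) -> float:
    """Glandular mass / total tissue mass (skin in denominator only).

    Homogenized mixture voxels count by their glandular mass share.
    """
    m_gland = 0.0
    m_total = 0.0
    v = phantom.voxel_volume_cm3()
    for lab, mat in phantom.label_map.items():
        n = np.count_nonzero(phantom.labels == lab)
        mass = n * mat.density * v
        m_total += mass
        m_gland += mass * phantom.glandular_share.get(lab, 0.0)
    if m_total == 0:
        raise ValueError("phantom has no tissue voxels")
    return m_gland / m_total


def homogenize(phantom: VoxelPhantom) -> VoxelPhantom:
    """Replace adipose+glandular voxels by their homogeneous mixture.

    The mixture fraction is the phantom's overall glandular fraction *by
    mass over the adipose+glandular compartment*; skin and air are left
    untouched.  Total tissue mass is conserved exactly (harmonic-mean
    mixture density).
    """
    v = phantom.voxel_volume_cm3()
    gl_labels = [l for l, s in phantom.glandular_share.items() if s > 0]
    ad_labels = [l for l, m in phantom.label_map.items()
                 if m.name == "adipose"]
    if not gl_labels:
        return phantom
    if not ad_labels:
        # already homogeneous (single mixture or pure glandular): fixed point
        return phantom
    m_g = sum(np.count_nonzero(phantom.labels == l)
              * phantom.label_map[l].density * v
              * phantom.glandular_share[l] for l in gl_labels)
    m_ga = sum(np.count_nonzero(phantom.labels == l)
               * phantom.label_map[l].density * v
               for l in set(gl_labels + ad_labels))
    w_g = m_g / m_ga
    mix = mix_by_mass([get_material("glandular"), get_material("adipose")],
                      [w_g, 1.0 - w_g], name="glandular_adipose_mix")
    new_labels = phantom.labels.copy()
    mix_label = 1
    for l in set(gl_labels + ad_labels):
        new_labels[phantom.labels == l] = mix_label
    label_map = {mix_label: mix}
    share = {mix_label: w_g}
    for l, m in phantom.label_map.items():
        if l not in set(gl_labels + ad_labels):
            label_map[l] = m
            share[l] = phantom.glandular_share[l]
    return VoxelPhantom(labels=new_labels, voxel_mm=phantom.voxel_mm,
                        label_map=label_map, origin_mm=phantom.origin_mm,
                        glandular_share=share)


class LayoutError(ValueError):
    pass


def tld_positions(phantom: VoxelPhantom, depth_cm: float,
                  layout: dict | None = None) -> list:
    """Sensitive volumes at the requested depth below the entrance surface.

    ``layout`` maps ``rows_y_mm`` (distances from the chest wall) and
    ``cols_x_mm`` (lateral offsets) to a grid of chip centers; the default
    is the documented 5 x 6 = 30 position grid.  Every chip must lie fully
    inside the phantom footprint (>= half a chip from any boundary).
    """
    layout = layout if layout is not None else DEFAULT_LAYOUT
    rows = list(layout.get("rows_y_mm", ()))
    cols = list(layout.get("cols_x_mm", ()))
    thickness_mm = phantom.thickness_cm * 10.0
    z = thickness_mm - depth_cm * 10.0 - CHIP_DIMS_MM[2] / 2.0
    out = []
    eps = 1e-6
    half = np.asarray(CHIP_DIMS_MM) / 2.0
    for idx, (y, x) in enumerate((y, x) for y in rows for x in cols):
        center = np.array([x, y, z])
        lo = center - half + eps
        hi = center + half - eps
        for corner in [(a, b, c) for a in (lo[0], hi[0])
                       for b in (lo[1], hi[1]) for c in (lo[2], hi[2])]:
            if phantom.label_at(corner) == AIR_LABEL:
                raise LayoutError(
                    f"position {idx} (x={x} mm, y={y} mm, depth={depth_cm} cm)"
                    " extends outside the phantom")
        out.append(SensitiveVolume(center_mm=tuple(center)))
    return out


# ---------------------------------------------------------------------------
# serialization: little-endian uint8 raw array + JSON sidecar

def write_phantom(phantom: VoxelPhantom, basepath: str) -> None:
    raw = basepath + ".raw"
    phantom.labels.astype("<u1").tofile(raw)
    sidecar = {
        "shape": list(phantom.labels.shape),
        "voxel_mm": phantom.voxel_mm,
        "origin_mm": list(phantom.origin_mm),
        "label_map": {
            str(lab): {"name": m.name, "density": m.density,
                       "mass_fractions": m.mass_fractions}
            for lab, m in phantom.label_map.items()},
        "glandular_share": {str(l): s
                            for l, s in phantom.glandular_share.items()},
    }
    with open(basepath + ".json", "w") as fh:
        json.dump(sidecar, fh, indent=1)


def read_phantom(basepath: str) -> VoxelPhantom:
    try:
        with open(basepath + ".json") as fh:
            side = json.load(fh)
    except (OSError, json.JSONDecodeError) as exc:
        raise PhantomFormatError(f"bad sidecar for {basepath}: {exc}")
    shape = tuple(side["shape"])
    n_expected = int(np.prod(shape))
    data = np.fromfile(basepath + ".raw", dtype="<u1")
    if data.size != n_expected:
        raise PhantomFormatError(
            f"raw file has {data.size} voxels, sidecar expects {n_expected}")
    label_map = {}
    for lab, spec in side["label_map"].items():
        label_map[int(lab)] = Material(spec["name"], spec["density"],
                                       dict(spec["mass_fractions"]))
    share = {int(l): float(s)
             for l, s in side.get("glandular_share", {}).items()}
    try:
        return VoxelPhantom(labels=data.reshape(shape),
                            voxel_mm=float(side["voxel_mm"]),
                            label_map=label_map,
                            origin_mm=tuple(side["origin_mm"]),
                            glandular_share=share)
    except PhantomFormatError:
        raise
    except (KeyError, ValueError) as exc:
        raise PhantomFormatError(str(exc))
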