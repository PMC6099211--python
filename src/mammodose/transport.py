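"""Photon Monte Carlo engine for the mammography irradiation geometry.

The beam is an isotropic point source collimated onto the detector
surface, with the anode heel effect applied as an amplitude modulation of
the emission (separable polynomial fits HE(d) = a + b d^2 + c d^4 along
the chest-wall->nipple and lateral axes, d in cm).  Photons traverse the
compression paddle (PET), the voxelized breast phantom and the carbon-
fiber support table; interactions are photoelectric absorption, free-
electron Klein-Nishina incoherent scattering and Thomson-law coherent
scattering, with transferred energy deposited locally (kerma
approximation, 1 keV cutoff).  Voxel traversal uses Woodcock (delta)
tracking on a per-energy majorant cross section.

Tallies: TLD-chip-sized boxes (track-length kerma estimator in the chip
material by default, or analog collision estimator), an optional 2D dose
map in an embedded TLD-material layer, and optional per-voxel energy
deposition for glandular-dose scoring.  Statistical uncertainties use
history-by-history (Sempau) variance accumulation.  Absolute doses are
obtained by normalizing the analytically computed incident air kerma per
history to the measured air kerma (scale factor).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from ._kernel import run_kernel
from .materials import (Material, get_material, muen_over_rho,
                        partial_mu_over_rho)
from .phantom import AIR_LABEL, SensitiveVolume, VoxelPhantom
from .spectrum import KEV_PER_G_TO_MGY, Spectrum, spectrum_avg_muen_ratio

__all__ = [
    "BeamGeometry", "HeelModel", "DEFAULT_HEEL_MODEL", "FLAT_HEEL",
    "Photon", "heel_weight", "fit_heel_model", "sample_primary", "run_mc",
    "tally_stats", "incident_air_kerma", "scale_factor", "dose_to_air",
    "score_dose_map", "MapSpec", "DoseResult", "DoseMap", "SimulationResult",
]


@dataclass(frozen=True)
class BeamGeometry:
    """Clinical mammography irradiation geometry (distances in mm)."""

    source_height_mm: float = 655.5
    field_x_mm: float = 300.0
    field_y_mm: float = 240.0
    paddle_thickness_mm: float = 3.0
    paddle_material_name: str = "pet"
    support_thickness_mm: float = 1.7
    support_material_name: str = "carbon_fiber"
    paddle_bottom_mm: float | None = None   # above detector plane

    def resolved_for(self, phantom: VoxelPhantom) -> "BeamGeometry":
        """Rest the paddle on the phantom top if its height is unset."""
        if self.paddle_bottom_mm is not None:
            top = self.support_thickness_mm + phantom.thickness_cm * 10.0
            if self.paddle_bottom_mm < top - 1e-9:
                raise ValueError("paddle below phantom top")
            return self
        return replace(self, paddle_bottom_mm=self.support_thickness_mm
                       + phantom.thickness_cm * 10.0)

    @property
    def paddle_top_mm(self) -> float:
        if self.paddle_bottom_mm is None:
            raise ValueError("paddle height unresolved; call resolved_for()")
        return self.paddle_bottom_mm + self.paddle_thickness_mm


@dataclass(frozen=True)
class HeelModel:
    """Separable heel-effect model HE(d) = a + b d^2 + c d^4 (d in cm).

    The y-axis distance is measured from the chest-wall edge, the x-axis
    distance from the field centerline; the two 1D fits are combined
    multiplicatively.
    """

    ay: float = 1.0
    by: float = 0.0
    cy: float = 0.0
    ax: float = 1.0
    bx: float = 0.0
    cx: float = 0.0
    r2y: float | None = None
    r2x: float | None = None


#: Surface-fit parameters measured on the clinical mammography unit the
#: engine models (28 kV W/Rh beam); d in cm.
DEFAULT_HEEL_MODEL = HeelModel(ay=1.0176, by=-0.0008, cy=-4.8146e-7,
                               ax=0.9971, bx=-0.0002, cx=-3.9390e-7)
FLAT_HEEL = HeelModel()


class HeelDomainError(ValueError):
    pass


def _he(d_cm, a, b, c):
    d2 = np.asarray(d_cm, float) ** 2
    return a + b * d2 + c * d2 * d2


def heel_weight(x_mm, y_mm, model: HeelModel = DEFAULT_HEEL_MODEL,
                normalization: float = 1.0):
    """Unnormalized heel amplitude HE_y(d_y) * HE_x(d_x) / normalization."""
    w = (_he(np.asarray(y_mm, float) / 10.0, model.ay, model.by, model.cy)
         * _he(np.abs(np.asarray(x_mm, float)) / 10.0,
               model.ax, model.bx, model.cx)) / normalization
    if np.any(w <= 0):
        raise HeelDomainError("heel model nonpositive inside the field")
    return float(w) if np.ndim(x_mm) == 0 and np.ndim(y_mm) == 0 else w


def _fit_axis(d_cm, values):
    d_cm = np.asarray(d_cm, float)
    values = np.asarray(values, float)
    if np.unique(np.abs(d_cm)).size < 3:
        raise ValueError("need >=3 distinct distances per axis")
    design = np.column_stack([np.ones_like(d_cm), d_cm ** 2, d_cm ** 4])
    coef, _, rank, _ = np.linalg.lstsq(design, values, rcond=None)
    if rank < 3:
        raise ValueError("rank-deficient heel design")
    pred = design @ coef
    ss_res = float(np.sum((values - pred) ** 2))
    ss_tot = float(np.sum((values - values.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return coef, r2


def fit_heel_model(y_d_cm, y_values, x_d_cm, x_values) -> HeelModel:
    """Least-squares fit of the quartic heel polynomial per axis.

    Constant data returns b = c = 0 with a = the constant (the quadratic
    and quartic terms are exactly zero in the least-squares solution).
    """
    (ay, by, cy), r2y = _fit_axis(y_d_cm, y_values)
    (ax, bx, cx), r2x = _fit_axis(x_d_cm, x_values)
    return HeelModel(ay=ay, by=by, cy=cy, ax=ax, bx=bx, cx=cx,
                     r2y=r2y, r2x=r2x)


@dataclass
class Photon:
    position_mm: np.ndarray
    direction: np.ndarray
    energy_kev: float
    alive: bool = True


def _heel_wmax(geometry: BeamGeometry, heel: HeelModel, n: int = 101):
    """Max (and min) of HE * cos(theta)/r^2 over the field."""
    x = np.linspace(-geometry.field_x_mm / 2, geometry.field_x_mm / 2, n)
    y = np.linspace(0.0, geometry.field_y_mm, n)
    xx, yy = np.meshgrid(x, y, indexing="ij")
    r2 = xx ** 2 + yy ** 2 + geometry.source_height_mm ** 2
    w = heel_weight(xx, yy, heel) * geometry.source_height_mm / r2 ** 1.5
    if np.any(w <= 0):
        raise HeelDomainError("heel model nonpositive inside the field")
    return float(w.max()) * 1.0001, w


def sample_primary(rng: np.random.Generator, geometry: BeamGeometry,
                   spectrum: Spectrum, heel: HeelModel = FLAT_HEEL,
                   n: int = 1):
    """Sample primary photons (positions are field-plane intercepts).

    Emission is isotropic within the collimation onto the detector field,
    with the heel amplitude applied by rejection at the detector-plane
    intercept; energies follow the spectrum's photon-fluence distribution.
    Returns a single Photon for n=1, else a list.
    """
    wmax, _ = _heel_wmax(geometry, heel)
    phi = spectrum.photon_fluence_per_bin
    cum = np.cumsum(phi)
    cum /= cum[-1]
    out = []
    src = np.array([0.0, 0.0, geometry.source_height_mm])
    while len(out) < n:
        m = max(2 * (n - len(out)), 16)
        xd = (rng.random(m) - 0.5) * geometry.field_x_mm
        yd = rng.random(m) * geometry.field_y_mm
        r2 = xd ** 2 + yd ** 2 + geometry.source_height_mm ** 2
        w = heel_weight(xd, yd, heel) * geometry.source_height_mm / r2 ** 1.5
        keep = rng.random(m) * wmax <= w
        for xi, yi in zip(xd[keep], yd[keep]):
            if len(out) >= n:
                break
            ib = int(np.searchsorted(cum, rng.random()))
            e = spectrum.bin_edges[ib] + rng.random() * \
                (spectrum.bin_edges[ib + 1] - spectrum.bin_edges[ib])
            pos = np.array([xi, yi, 0.0])
            d = pos - src
            d /= np.linalg.norm(d)
            out.append(Photon(position_mm=pos, direction=d, energy_kev=e))
    return out[0] if n == 1 else out


# ---------------------------------------------------------------------------
# results containers

def tally_stats(sum_d, sum_d2, n):
    """History-by-history (Sempau) mean and relative standard uncertainty.

    mean = S1/N; sigma_mean^2 = (1/N) [S2/N - (S1/N)^2].  Returns
    (mean_per_history, relative_sigma); the relative uncertainty is NaN
    (with a warning) where the mean is zero.
    """
    if n < 2:
        raise ValueError("need at least 2 histories for variance")
    s1 = np.asarray(sum_d, float)
    s2 = np.asarray(sum_d2, float)
    mean = s1 / n
    var = np.maximum(s2 / n - mean ** 2, 0.0) / n
    sigma = np.sqrt(var)
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.where(mean != 0, sigma / np.abs(mean), np.nan)
    if np.any(mean == 0):
        warnings.warn("zero-mean tally: relative uncertainty undefined",
                      RuntimeWarning)
    if np.ndim(sum_d) == 0:
        return float(mean), float(rel)
    return mean, rel


@dataclass
class DoseResult:
    """Per-tally scored dose (keV/g per history) with Sempau statistics."""

    sum_d: np.ndarray
    sum_d2: np.ndarray
    n_histories: int
    volumes: tuple = ()

    @property
    def mean_per_history(self) -> np.ndarray:
        """Mean dose per history, mGy."""
        return self.sum_d / self.n_histories * KEV_PER_G_TO_MGY

    @property
    def rel_sigma(self) -> np.ndarray:
        return tally_stats(self.sum_d, self.sum_d2, self.n_histories)[1]

    def absolute(self, scale: float) -> np.ndarray:
        """Absolute dose in mGy after applying the kerma scale factor."""
        return self.mean_per_history * scale


@dataclass
class DoseMap:
    """2D dose map in the embedded TLD-material layer."""

    energy_sum: np.ndarray        # keV per pixel
    energy_sum2: np.ndarray
    pixel_mass_g: float
    pitch_mm: float
    origin_mm: tuple
    n_histories: int

    @property
    def dose_per_history(self) -> np.ndarray:
        """mGy per history per pixel."""
        return (self.energy_sum / self.n_histories / self.pixel_mass_g
                * KEV_PER_G_TO_MGY)

    @property
    def rel_sigma(self) -> np.ndarray:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return tally_stats(self.energy_sum, self.energy_sum2,
                               self.n_histories)[1]

    def absolute(self, scale: float) -> np.ndarray:
        return self.dose_per_history * scale


@dataclass
class SimulationResult:
    n_histories: int
    seed: int
    tallies: DoseResult | None
    dose_map: DoseMap | None
    edep_voxels_kev: np.ndarray | None
    gland_sum: float
    gland_sum2: float
    emitted_kev: float
    deposited_kev: float
    escaped_kev: float


@dataclass(frozen=True)
class MapSpec:
    """Pixelized TLD-material scoring layer at a given depth."""

    depth_cm: float
    pitch_mm: float = 1.0
    x0_mm: float = -100.0
    y0_mm: float = 0.0
    nx: int = 200
    ny: int = 120
    thickness_mm: float = 0.38


# ---------------------------------------------------------------------------
# the engine

_E0 = 1.0
_DE = 0.1


def _material_tables(mats, kvp):
    n_e = int(np.ceil((kvp - _E0) / _DE)) + 2
    centers = _E0 + (np.arange(n_e) + 0.5) * _DE
    centers = np.minimum(centers, 49.9)
    n_mat = len(mats)
    mu_tot = np.zeros((n_mat, n_e))
    mu_pe = np.zeros((n_mat, n_e))
    mu_incoh = np.zeros((n_mat, n_e))
    rho = np.zeros(n_mat)
    for i, m in enumerate(mats):
        rho[i] = m.density
        f = m.density / 10.0  # cm^2/g -> 1/mm
        mu_tot[i] = partial_mu_over_rho(m, centers, "total") * f
        mu_pe[i] = partial_mu_over_rho(m, centers, "pe") * f
        mu_incoh[i] = partial_mu_over_rho(m, centers, "incoh") * f
    return centers, mu_tot, mu_pe, mu_incoh, rho


def run_mc(phantom: VoxelPhantom, geometry: BeamGeometry, spectrum: Spectrum,
           tallies=None, n_histories: int = 0, seed: int | None = None,
           heel: HeelModel = FLAT_HEEL, map_spec: MapSpec | None = None,
           score_voxel_edep: bool = False, collision_tallies: bool = False,
           cutoff_kev: float = 1.0) -> SimulationResult:
    """Run the photon Monte Carlo and return scored doses.

    ``tallies`` is a list of SensitiveVolume (phantom-frame coordinates);
    their dose is scored with a track-length kerma estimator in the chip
    material (chips are not physically embedded), or analog collision
    deposition if ``collision_tallies``.  ``map_spec`` embeds a physical
    TLD-material layer and scores a 2D collision-deposition map.  Seeds
    are mandatory for reproducibility.
    """
    if seed is None:
        raise ValueError("an explicit integer seed is required")
    if n_histories < 1:
        raise ValueError("n_histories must be >= 1")
    geometry = geometry.resolved_for(phantom)
    tallies = list(tallies or [])

    # material stack: 0 air, 1 paddle, 2 support, 3.. phantom labels (+ TLD)
    mats = [get_material("air"),
            get_material(geometry.paddle_material_name),
            get_material(geometry.support_material_name)]
    lab2mat = np.zeros(256, dtype=np.int64)
    for lab, m in sorted(phantom.label_map.items()):
        lab2mat[lab] = len(mats)
        mats.append(m)
    tld = get_material("tld")
    map_mat_idx = len(mats)
    if map_spec is not None:
        mats.append(tld)

    centers, mu_tot, mu_pe, mu_incoh, rho = _material_tables(mats,
                                                             spectrum.kvp)
    mu_maj = mu_tot.max(axis=0)

    # box tallies in the global frame (phantom z + support offset)
    zoff = geometry.support_thickness_mm
    n_box = len(tallies)
    boxes = np.zeros((max(n_box, 1), 6))
    box_muen = np.zeros((max(n_box, 1), centers.size))
    box_vol = np.ones(max(n_box, 1))
    for k, sv in enumerate(tallies):
        lo, hi = sv.bounds_mm
        boxes[k] = [lo[0], hi[0], lo[1], hi[1], lo[2] + zoff, hi[2] + zoff]
        if sv.volume_cm3() <= 0:
            raise ValueError(f"tally {k} has zero volume")
        box_vol[k] = sv.volume_cm3()
        box_muen[k] = muen_over_rho(get_material(sv.material_name), centers)

    # spectrum sampling arrays
    phi = spectrum.photon_fluence_per_bin
    if phi.sum() <= 0:
        raise ValueError("spectrum has zero fluence")
    cum_phi = np.cumsum(phi)
    cum_phi /= cum_phi[-1]

    wmax, _ = _heel_wmax(geometry, heel)

    # world bounding box
    ox, oy, ozp = phantom.origin_mm
    ext_lo, ext_hi = phantom.extent_mm
    margin = 50.0
    wx0 = min(-geometry.field_x_mm / 2, ext_lo[0]) - margin
    wx1 = max(geometry.field_x_mm / 2, ext_hi[0]) + margin
    wy0 = -margin
    wy1 = max(geometry.field_y_mm, ext_hi[1]) + margin
    wz1 = geometry.paddle_top_mm

    ms = map_spec
    if ms is not None:
        z1 = zoff + phantom.thickness_cm * 10.0 - ms.depth_cm * 10.0
        z0 = z1 - ms.thickness_mm
        map_args = (True, ms.x0_mm, ms.y0_mm, ms.pitch_mm, ms.nx, ms.ny,
                    z0, z1, map_mat_idx)
    else:
        map_args = (False, 0.0, 0.0, 1.0, 1, 1, 0.0, 0.0, 0)

    gland_share = np.zeros(256)
    for lab, s in phantom.glandular_share.items():
        gland_share[lab] = s

    out = run_kernel(
        int(seed), int(n_histories),
        geometry.source_height_mm, geometry.field_x_mm / 2,
        geometry.field_y_mm,
        heel.ay, heel.by, heel.cy, heel.ax, heel.bx, heel.cx, wmax,
        cum_phi, spectrum.bin_edges,
        _E0, _DE, mu_tot, mu_pe, mu_incoh, mu_maj, rho,
        geometry.support_thickness_mm, geometry.paddle_bottom_mm,
        geometry.paddle_top_mm,
        float(ox), float(oy), float(ozp) + zoff, phantom.voxel_mm,
        phantom.labels, lab2mat,
        wx0, wx1, wy0, wy1, 0.0, wz1,
        boxes, box_muen, box_vol, bool(collision_tallies),
        *map_args,
        bool(score_voxel_edep), gland_share, float(cutoff_kev))

    (tally_sum, tally_sum2, map_sum, map_sum2, edep_vox,
     gland_sum, gland_sum2, emitted, edep_total, escaped) = out

    dose = None
    if n_box:
        dose = DoseResult(sum_d=tally_sum[:n_box], sum_d2=tally_sum2[:n_box],
                          n_histories=n_histories, volumes=tuple(tallies))
    dmap = None
    if ms is not None:
        pixel_mass = tld.density * (ms.pitch_mm / 10.0) ** 2 \
            * (ms.thickness_mm / 10.0)
        dmap = DoseMap(energy_sum=map_sum.reshape(ms.nx, ms.ny),
                       energy_sum2=map_sum2.reshape(ms.nx, ms.ny),
                       pixel_mass_g=pixel_mass, pitch_mm=ms.pitch_mm,
                       origin_mm=(ms.x0_mm, ms.y0_mm), n_histories=n_histories)
    return SimulationResult(
        n_histories=n_histories, seed=seed, tallies=dose, dose_map=dmap,
        edep_voxels_kev=edep_vox if score_voxel_edep else None,
        gland_sum=float(gland_sum), gland_sum2=float(gland_sum2),
        emitted_kev=float(emitted), deposited_kev=float(edep_total),
        escaped_kev=float(escaped))


def score_dose_map(phantom: VoxelPhantom, geometry: BeamGeometry,
                   spectrum: Spectrum, depth_cm: float, n_histories: int,
                   seed: int, pitch_mm: float = 1.0,
                   heel: HeelModel = FLAT_HEEL,
                   map_extent=None) -> DoseMap:
    """2D collision-deposition dose map in an embedded TLD-material layer.

    The layer (default 0.38 mm thick, 12 x 20 cm footprint clipped to the
    requested extent) physically replaces the phantom material at the
    given depth, as in the physical film measurement.
    """
    thickness_mm = phantom.thickness_cm * 10.0
    if not 0 <= depth_cm * 10.0 <= thickness_mm - 0.38:
        raise ValueError("scoring layer outside phantom")
    if map_extent is None:
        ext_lo, ext_hi = phantom.extent_mm
        x0, y0 = max(-100.0, ext_lo[0]), 0.0
        nx = int(min(200.0, ext_hi[0] - ext_lo[0]) / pitch_mm)
        ny = int(min(120.0, ext_hi[1]) / pitch_mm)
    else:
        x0, y0, nx, ny = map_extent
    ms = MapSpec(depth_cm=depth_cm, pitch_mm=pitch_mm, x0_mm=x0, y0_mm=y0,
                 nx=nx, ny=ny)
    res = run_mc(phantom, geometry, spectrum, n_histories=n_histories,
                 seed=seed, heel=heel, map_spec=ms)
    return res.dose_map


# ---------------------------------------------------------------------------
# absolute normalization

def incident_air_kerma(geometry: BeamGeometry, spectrum: Spectrum,
                       heel: HeelModel = FLAT_HEEL,
                       region_center_mm=(0.0, 40.0),
                       region_size_mm: float = 30.0,
                       n_grid: int = 21) -> float:
    """Analytic incident air kerma per history (mGy), primary beam only.

    Average air kerma over a square region (default 3 x 3 cm^2, laterally
    centered, 4 cm from the chest wall) at the bottom surface of the
    compression paddle, accounting for inverse square, the heel amplitude,
    paddle transmission and the air column -- with no phantom in the beam.
    The per-history normalization matches the Monte Carlo source sampling
    (one history = one photon emitted into the collimated field).
    """
    if geometry.paddle_bottom_mm is None:
        raise ValueError("geometry needs a resolved paddle height")
    zr = geometry.paddle_bottom_mm
    zs = geometry.source_height_mm
    cxr, cyr = region_center_mm
    half = region_size_mm / 2.0

    # region must project inside the collimated field
    proj = zs / (zs - zr)
    for px, py in [(cxr - half, cyr - half), (cxr + half, cyr + half)]:
        if abs(px * proj) > geometry.field_x_mm / 2 or not \
                0 <= py * proj <= geometry.field_y_mm:
            raise ValueError("scoring region outside the field")

    # emission normalization over the field solid angle (with heel)
    ng = 161
    xf = np.linspace(-geometry.field_x_mm / 2, geometry.field_x_mm / 2, ng)
    yf = np.linspace(0.0, geometry.field_y_mm, ng)
    xx, yy = np.meshgrid(xf, yf, indexing="ij")
    r2 = xx ** 2 + yy ** 2 + zs ** 2
    dom = heel_weight(xx, yy, heel) * zs / r2 ** 1.5
    i_omega = float(np.trapezoid(np.trapezoid(dom, yf, axis=1), xf))

    air = get_material("air")
    paddle = get_material(geometry.paddle_material_name)
    e = spectrum.centers
    phi_frac = spectrum.photon_fluence_per_bin
    phi_frac = phi_frac / phi_frac.sum()
    muen_air = muen_over_rho(air, e)
    mu_air = partial_mu_over_rho(air, e, "total") * air.density / 10.0  # 1/mm
    mu_pad = partial_mu_over_rho(paddle, e, "total") * paddle.density / 10.0

    xs = np.linspace(cxr - half, cxr + half, n_grid)
    ys = np.linspace(cyr - half, cyr + half, n_grid)
    k_acc = np.zeros((n_grid, n_grid))
    for i, xq in enumerate(xs):
        for j, yq in enumerate(ys):
            rq = np.sqrt(xq ** 2 + yq ** 2 + (zs - zr) ** 2)
            cost = (zs - zr) / rq
            px, py = xq * zs / (zs - zr), yq * zs / (zs - zr)
            he = heel_weight(px, py, heel)
            fluence = he / (i_omega * rq ** 2)    # per mm^2 per history
            slant = geometry.paddle_thickness_mm / cost
            trans = np.exp(-mu_pad * slant - mu_air * (rq - slant))
            # fluence mm^-2 -> cm^-2 (x100)
            k_acc[i, j] = np.sum(phi_frac * trans * e * muen_air) \
                * fluence * 100.0
    return float(k_acc.mean() * KEV_PER_G_TO_MGY)


def scale_factor(measured_kerma_mgy: float,
                 simulated_kerma_per_history_mgy: float) -> float:
    """Histories-equivalent normalization: measured / simulated-per-history."""
    if measured_kerma_mgy <= 0 or simulated_kerma_per_history_mgy <= 0:
        raise ValueError("kerma values must be positive")
    return measured_kerma_mgy / simulated_kerma_per_history_mgy


def dose_to_air(d_mc, hardened_spectrum: Spectrum,
                detector_material: Material | None = None) -> float:
    """Convert dose scored in the dosimeter material to dose in air.

    D_air = D_MC * <muen/rho>_air / <muen/rho>_TLD, with the spectrum
    averages taken over the supplied depth-hardened spectrum.
    """
    detector_material = detector_material or get_material("tld")
    ratio = spectrum_avg_muen_ratio(hardened_spectrum, get_material("air"),
                                    detector_material)
    return d_mc * ratio
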