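"""Depth-dose summaries, average glandular dose and agreement testing."""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .phantom import VoxelPhantom

__all__ = [
    "DepthDoseTable", "RegionHistogram", "depth_dose_summary", "agd",
    "dose_histogram", "agreement_check",
]


@dataclass(frozen=True)
class DepthDoseTable:
    """Per-depth mean dose over the dosimeter positions."""

    depths_cm: np.ndarray
    means: np.ndarray                    # mean over positions at each depth
    spreads: np.ndarray                  # standard deviation over positions
    values: dict                         # depth -> per-position dose array

    def percent_decrease(self, d1: float, d2: float) -> float:
        """100 * (1 - mean(d2)/mean(d1)); invariant to global rescaling."""
        try:
            i1 = int(np.flatnonzero(np.isclose(self.depths_cm, d1))[0])
            i2 = int(np.flatnonzero(np.isclose(self.depths_cm, d2))[0])
        except IndexError:
            raise KeyError(f"depth {d1} or {d2} cm not present")
        return 100.0 * (1.0 - self.means[i2] / self.means[i1])


def depth_dose_summary(results_by_depth: dict) -> DepthDoseTable:
    """Summarize per-position doses keyed by depth (cm).

    ``results_by_depth`` maps depth -> array of per-position doses (e.g.
    the 30 dosimeter positions of one layer).
    """
    if len(results_by_depth) < 2:
        raise ValueError("need at least two depths")
    depths = np.array(sorted(results_by_depth))
    values = {d: np.asarray(results_by_depth[d], float) for d in depths}
    means = np.array([values[d].mean() for d in depths])
    spreads = np.array([values[d].std(ddof=1) if values[d].size > 1 else 0.0
                        for d in depths])
    if np.any(means <= 0):
        raise ValueError("nonpositive mean dose")
    return DepthDoseTable(depths_cm=depths, means=means, spreads=spreads,
                          values=values)


def agd(phantom: VoxelPhantom, energy_dep_kev: np.ndarray,
        spectrum=None) -> float:
    """Average glandular dose (mass-weighted) from a per-voxel energy map.

    For purely glandular voxels the deposited energy counts in full.  For
    homogenized glandular/adipose mixture voxels (glandular mass share s in
    (0,1)) the energy is partitioned to the glandular component by the
    standard mass-energy-absorption weighting

        G = s * <muen/rho>_glandular / <muen/rho>_mixture,

    with the averages weighted by the differential energy fluence of the
    irradiating ``spectrum`` (required whenever mixture labels are present:
    dose-to-mixture is not dose-to-glandular-tissue).  Skin and adipose
    never contribute.  Returns dose in mGy per unit of the energy map (keV).
    """
    from .materials import get_material, muen_over_rho
    from .spectrum import KEV_PER_G_TO_MGY
    if energy_dep_kev.shape != phantom.labels.shape:
        raise ValueError("energy map shape does not match phantom")
    v = phantom.voxel_volume_cm3()
    e_gland = 0.0
    m_gland = 0.0
    for lab, share in phantom.glandular_share.items():
        if share <= 0 or lab not in phantom.label_map:
            continue
        mask = phantom.labels == lab
        mat = phantom.label_map[lab]
        mass = mat.density * v
        g = share
        if share < 1.0:
            if spectrum is None:
                raise ValueError(
                    "mixture voxels need the irradiation spectrum to "
                    "partition deposited energy to the glandular component")
            w = spectrum.psi_E * spectrum.widths
            e_grid = spectrum.centers
            gl = get_material("glandular")
            num = np.sum(w * muen_over_rho(gl, e_grid))
            den = np.sum(w * muen_over_rho(mat, e_grid))
            g = share * num / den
        e_gland += g * float(energy_dep_kev[mask].sum())
        m_gland += share * mass * int(np.count_nonzero(mask))
    if m_gland == 0:
        raise ValueError("phantom has no glandular voxels")
    return e_gland / m_gland * KEV_PER_G_TO_MGY


@dataclass(frozen=True)
class RegionHistogram:
    """Dose-value histogram split at two thresholds (default 3 and 8 mGy)."""

    thresholds: tuple
    fractions: tuple                    # fraction of values per region
    histogram: np.ndarray               # counts normalized to unit maximum
    bin_edges: np.ndarray


def dose_histogram(map_mgy, thresholds=(3.0, 8.0), bins=100) -> RegionHistogram:
    """Three-region dose histogram, normalized to unit maximum.

    Regions: below ``thresholds[0]``, between the thresholds, and above
    ``thresholds[1]`` (e.g. unirradiated area / in-phantom / free-in-air).
    """
    values = np.asarray(map_mgy, float).ravel()
    values = values[np.isfinite(values)]
    if values.size == 0:
        raise ValueError("empty dose map")
    t1, t2 = thresholds
    if not t1 < t2:
        raise ValueError("thresholds must be ascending")
    n = values.size
    fracs = (float(np.count_nonzero(values < t1)) / n,
             float(np.count_nonzero((values >= t1) & (values <= t2))) / n,
             float(np.count_nonzero(values > t2)) / n)
    counts, edges = np.histogram(values, bins=bins)
    peak = counts.max() if counts.max() > 0 else 1
    return RegionHistogram(thresholds=(t1, t2), fractions=fracs,
                           histogram=counts / peak, bin_edges=edges)


def agreement_check(meas, u_meas, sim, u_sim, k: float = 1.0):
    """Measurement/simulation agreement at k combined standard uncertainties.

    z = |meas - sim| / sqrt(u_meas^2 + u_sim^2); passes if z <= k.
    Uncertainties are absolute (same units as the values).
    """
    u_meas = np.asarray(u_meas, float)
    u_sim = np.asarray(u_sim, float)
    if np.any(u_meas <= 0) or np.any(u_sim <= 0):
        raise ValueError("uncertainties must be positive")
    z = np.abs(np.asarray(meas, float) - np.asarray(sim, float)) \
        / np.sqrt(u_meas ** 2 + u_sim ** 2)
    ok = z <= k
    if np.ndim(z) == 0:
        return float(z), bool(ok)
    return z, ok
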