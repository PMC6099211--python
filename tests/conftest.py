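import numpy as np
import pytest

from mammodose import materials as M
from mammodose import phantom as P
from mammodose import spectrum as S
from mammodose import transport as T


@pytest.fixture(scope="session")
def tuned_spectrum():
    """28 kV W-anode model beam, Rh filter tuned to first HVL 0.55 mm Al."""
    s = S.generate_bremsstrahlung(28.0)
    t = S.tune_filter(s, M.get_material("rhodium"), target_hvl_mm=0.55,
                      bounds_mm=(0.02, 0.08))
    tuned = S.attenuate(s, M.get_material("rhodium"), t)
    tuned = tuned.scaled(1.0 / tuned.photon_fluence)
    object.__setattr__(tuned, "rh_thickness_tuned_mm", t)
    return tuned


@pytest.fixture(scope="session")
def homog_phantom():
    """Measurement-configuration homogeneous phantom (fits the 30-position
    layout, hence radius 130 mm)."""
    return P.build_homogeneous(radius_mm=130.0, thickness_cm=5.0,
                               voxel_mm=2.0)


@pytest.fixture(scope="session")
def geometry(homog_phantom):
    return T.BeamGeometry().resolved_for(homog_phantom)


def mean_and_sigma(dose_result, sel):
    """Mean over a set of chips and its propagated absolute sigma."""
    m = dose_result.mean_per_history[sel]
    rs = dose_result.rel_sigma[sel]
    mean = m.mean()
    sigma = np.sqrt(np.nansum((m * rs) ** 2)) / m.size
    return mean, sigma


@pytest.fixture(scope="session")
def depth_run(homog_phantom, geometry, tuned_spectrum):
    """One 6e6-history run of the full measurement configuration:
    30 chips at each depth 0..4 cm, heel effect and paddle included."""
    depths = [0.0, 1.0, 2.0, 3.0, 4.0]
    tallies = []
    for d in depths:
        tallies.extend(P.tld_positions(homog_phantom, d))
    res = T.run_mc(homog_phantom, geometry, tuned_spectrum, tallies=tallies,
                   n_histories=6_000_000, seed=20260922,
                   heel=T.DEFAULT_HEEL_MODEL)
    return depths, res


@pytest.fixture(scope="session")
def synthetic_pair():
    """Synthetic anthropomorphic phantom (10.9% glandular) and its
    homogenized counterpart, with matched seeded simulations scoring
    per-voxel energy deposition for glandular-dose comparison."""
    ph = P.build_synthetic_breast(seed=4, thickness_cm=4.5,
                                  target_glandularity=0.109,
                                  radius_mm=60.0, voxel_mm=2.0)
    hom = P.homogenize(ph)
    geo = T.BeamGeometry().resolved_for(ph)
    s = S.generate_bremsstrahlung(28.0)
    s = S.attenuate(s, M.get_material("rhodium"), 0.05)
    s = s.scaled(1.0 / s.photon_fluence)
    runs = {}
    for key, phant in (("het", ph), ("hom", hom)):
        runs[key] = T.run_mc(phant, geo, s, n_histories=500_000, seed=99,
                             heel=T.DEFAULT_HEEL_MODEL,
                             score_voxel_edep=True)
    return {"het": ph, "hom": hom, "runs": runs, "spectrum": s}
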