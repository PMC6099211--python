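import numpy as np
import pytest

from mammodose import materials as M
from mammodose import phantom as P


# ---------------------------------------------------------------------------
# homogeneous phantom

def test_homogeneous_volume_converges_to_analytic():
    """Voxelized semicylinder volume approaches (1/2) pi r^2 h; halving the
    voxel size at least halves the error."""
    analytic = 0.5 * np.pi * 10.0 ** 2 * 5.0          # cm^3
    errs = []
    for v in (2.0, 1.0):
        ph = P.build_homogeneous(radius_mm=100.0, thickness_cm=5.0,
                                 voxel_mm=v)
        vol = np.count_nonzero(ph.labels) * ph.voxel_volume_cm3()
        errs.append(abs(vol - analytic) / analytic)
    assert errs[1] < 0.01
    assert errs[1] <= errs[0]


def test_homogeneous_uniform_label_and_material():
    ph = P.build_homogeneous(radius_mm=50.0, thickness_cm=2.0, voxel_mm=1.0)
    inside = ph.labels[ph.labels != P.AIR_LABEL]
    assert set(np.unique(inside)) == {1}
    assert ph.label_map[1].name == "breast_50_50"


def test_homogeneous_rejects_degenerate_dimensions():
    with pytest.raises(ValueError):
        P.build_homogeneous(radius_mm=100.0, thickness_cm=0.0)
    with pytest.raises(ValueError):
        P.build_homogeneous(radius_mm=5.0, thickness_cm=0.5, voxel_mm=20.0)


# ---------------------------------------------------------------------------
# synthetic anthropomorphic phantom

@pytest.mark.parametrize("seed", range(10))
def test_synthetic_breast_hits_target_glandularity(seed):
    ph = P.build_synthetic_breast(seed=seed, thickness_cm=4.5,
                                  target_glandularity=0.109,
                                  radius_mm=60.0, voxel_mm=2.0)
    assert 0.104 <= P.glandular_mass_fraction(ph) <= 0.114


def test_synthetic_breast_deterministic_by_seed():
    a = P.build_synthetic_breast(seed=11, voxel_mm=2.0, radius_mm=60.0)
    b = P.build_synthetic_breast(seed=11, voxel_mm=2.0, radius_mm=60.0)
    assert np.array_equal(a.labels, b.labels)
    c = P.build_synthetic_breast(seed=12, voxel_mm=2.0, radius_mm=60.0)
    assert not np.array_equal(a.labels, c.labels)


def test_synthetic_breast_zero_target_is_pure_adipose_plus_skin():
    ph = P.build_synthetic_breast(seed=0, target_glandularity=0.0,
                                  voxel_mm=2.0, radius_mm=60.0)
    present = set(np.unique(ph.labels))
    assert P.GLANDULAR_LABEL not in present
    assert {P.ADIPOSE_LABEL, P.SKIN_LABEL} <= present
    assert P.glandular_mass_fraction(ph) == 0.0


def test_synthetic_breast_has_skin_shell_and_central_glands():
    ph = P.build_synthetic_breast(seed=3, voxel_mm=1.0, radius_mm=60.0)
    # skin occupies the top and bottom faces inside the footprint
    inside_col = ph.labels[:, :, 0] != P.AIR_LABEL
    assert np.all(ph.labels[:, :, 0][inside_col] == P.SKIN_LABEL)
    assert np.all(ph.labels[:, :, -1][inside_col] == P.SKIN_LABEL)
    # glandular tissue is denser (per unit thickness) at mid-depth than in
    # the outer thirds
    nz = ph.labels.shape[2]
    mid = np.count_nonzero(ph.labels[:, :, nz // 3:2 * nz // 3]
                           == P.GLANDULAR_LABEL)
    outer = np.count_nonzero(ph.labels == P.GLANDULAR_LABEL) - mid
    n_mid = 2 * nz // 3 - nz // 3
    assert mid / n_mid > outer / (nz - n_mid)


# ---------------------------------------------------------------------------
# glandular fraction and homogenization

def test_glandular_mass_fraction_trivia():
    gl = M.get_material("glandular")
    labels = np.ones((4, 4, 4), dtype=np.uint8)
    ph = P.VoxelPhantom(labels=labels, voxel_mm=1.0, label_map={1: gl})
    assert P.glandular_mass_fraction(ph) == pytest.approx(1.0)

    # 50/50 by volume with equal densities -> 0.5 by mass
    a = M.Material("glandular", 1.0, dict(gl.mass_fractions))
    b = M.Material("other", 1.0, {"O": 1.0})
    labels2 = np.ones((4, 4, 4), dtype=np.uint8)
    labels2[:2] = 2
    ph2 = P.VoxelPhantom(labels=labels2, voxel_mm=1.0,
                         label_map={1: a, 2: b})
    assert P.glandular_mass_fraction(ph2) == pytest.approx(0.5)


def test_homogenize_preserves_glandular_fraction_and_mass():
    ph = P.build_synthetic_breast(seed=5, voxel_mm=2.0, radius_mm=60.0)
    hom = P.homogenize(ph)
    g0 = P.glandular_mass_fraction(ph)
    g1 = P.glandular_mass_fraction(hom)
    assert abs(g1 - g0) < 1e-3

    def tissue_mass(p):
        v = p.voxel_volume_cm3()
        return sum(np.count_nonzero(p.labels == l) * m.density * v
                   for l, m in p.label_map.items())
    assert tissue_mass(hom) == pytest.approx(tissue_mass(ph), rel=5e-3)
    # interior is a single uniform mixture at the overall glandular fraction
    interior = [m for m in hom.label_map.values()
                if m.name == "glandular_adipose_mix"]
    assert len(interior) == 1


def test_homogenize_is_fixed_point():
    ph = P.build_synthetic_breast(seed=5, voxel_mm=2.0, radius_mm=60.0)
    hom = P.homogenize(ph)
    again = P.homogenize(hom)
    assert np.array_equal(again.labels, hom.labels)
    assert {m.name for m in again.label_map.values()} == \
        {m.name for m in hom.label_map.values()}


# ---------------------------------------------------------------------------
# dosimeter layout

def test_default_layout_gives_30_chips_inside_footprint():
    ph = P.build_homogeneous(radius_mm=130.0, thickness_cm=5.0, voxel_mm=1.0)
    chips = P.tld_positions(ph, depth_cm=2.0)
    assert len(chips) == 30
    for sv in chips:
        x, y, z = sv.center_mm
        # at least half a chip from the lateral boundary
        far = np.hypot(abs(x) + 1.6, y + 1.6)
        assert far <= 130.0
        assert y - 1.6 >= 0.0
        assert 0.0 <= z <= 50.0


def test_empty_layout_gives_no_chips():
    ph = P.build_homogeneous(radius_mm=130.0, thickness_cm=5.0, voxel_mm=1.0)
    assert P.tld_positions(ph, 1.0, layout={"rows_y_mm": [],
                                            "cols_x_mm": []}) == []


def test_layout_outside_footprint_names_the_position():
    ph = P.build_homogeneous(radius_mm=100.0, thickness_cm=5.0, voxel_mm=1.0)
    with pytest.raises(P.LayoutError, match="position 0"):
        P.tld_positions(ph, 1.0, layout={"rows_y_mm": [99.0],
                                         "cols_x_mm": [0.0]})


# ---------------------------------------------------------------------------
# serialization

def test_phantom_round_trip(tmp_path):
    ph = P.build_synthetic_breast(seed=2, voxel_mm=2.0, radius_mm=60.0)
    base = str(tmp_path / "ph")
    P.write_phantom(ph, base)
    back = P.read_phantom(base)
    assert np.array_equal(back.labels, ph.labels)
    assert back.voxel_mm == ph.voxel_mm
    assert back.origin_mm == tuple(ph.origin_mm)
    assert back.glandular_share == ph.glandular_share
    for lab, m in ph.label_map.items():
        assert back.label_map[lab].name == m.name
        assert back.label_map[lab].density == m.density


def test_truncated_raw_file_is_a_format_error(tmp_path):
    ph = P.build_homogeneous(radius_mm=30.0, thickness_cm=1.0, voxel_mm=2.0)
    base = str(tmp_path / "ph")
    P.write_phantom(ph, base)
    raw = (tmp_path / "ph.raw").read_bytes()
    (tmp_path / "ph.raw").write_bytes(raw[:-10])
    with pytest.raises(P.PhantomFormatError):
        P.read_phantom(base)


def test_sidecar_missing_label_is_a_format_error(tmp_path):
    import json
    ph = P.build_homogeneous(radius_mm=30.0, thickness_cm=1.0, voxel_mm=2.0)
    base = str(tmp_path / "ph")
    P.write_phantom(ph, base)
    side = json.loads((tmp_path / "ph.json").read_text())
    del side["label_map"]["1"]
    (tmp_path / "ph.json").write_text(json.dumps(side))
    with pytest.raises(P.PhantomFormatError):
        P.read_phantom(base)
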