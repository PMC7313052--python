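"""Transmembrane helix geometry: axes, bends, tilts, crossing angles."""

import numpy as np
import pytest

import sercakit as sk
from sercakit.geometry import rotation_about_axis
from sercakit.structure import DomainDefinition, select_coordinates
from sercakit.synthetic import HelixSpec, make_ideal_helix, make_kinked_helix

Z = np.array([0.0, 0.0, 1.0])


def _ca(structure, lo, hi):
    return select_coordinates(structure, DomainDefinition("h", ((lo, hi),)), atoms="CA").coords


def test_helix_axis_along_construction_axis(ideal_helix):
    axis, centroid = sk.helix_axis(_ca(ideal_helix, 1, 20))
    assert np.dot(axis, Z) == pytest.approx(1.0, abs=1e-3)
    assert np.allclose(centroid[:2], 0.0, atol=0.5)


def test_helix_axis_rotates_with_structure(ideal_helix):
    rot = rotation_about_axis([1.0, 0.0, 0.0], 30.0)
    moved = ideal_helix.transformed(rot, np.zeros(3))
    axis, _ = sk.helix_axis(_ca(moved, 1, 20))
    base, _ = sk.helix_axis(_ca(ideal_helix, 1, 20))
    assert np.dot(axis, rot @ base) == pytest.approx(1.0, abs=1e-9)


def test_noisy_helix_axis_within_two_degrees():
    noisy = make_ideal_helix(HelixSpec(n_residues=25, noise_sd=0.3, seed=3))
    axis, _ = sk.helix_axis(_ca(noisy, 1, 25))
    ang = np.degrees(np.arccos(abs(np.dot(axis, Z))))
    assert ang < 2.0


def test_axis_requires_enough_points():
    with pytest.raises(ValueError):
        sk.helix_axis(np.zeros((4, 3)))


def test_straight_helix_bend_below_five_degrees(ideal_helix):
    assert sk.bending_angle(_ca(ideal_helix, 1, 20)) < 5.0


@pytest.mark.parametrize("kink", [20.0, 40.0, 60.0, 90.0])
def test_kinked_helix_bend_recovered_within_three_degrees(kink):
    s, truth = make_kinked_helix(
        HelixSpec(n_residues=20), HelixSpec(n_residues=20), kink
    )
    ca = _ca(s, 1, 40)
    assert sk.bending_angle(ca) == pytest.approx(truth["kink_angle_deg"], abs=3.0)


def test_bend_monotone_under_noise():
    """Bend of an ideal helix grows from ~0 with noise amplitude (seeded)."""
    bends = []
    for sd in (0.0, 0.5, 1.5):
        bs = []
        for seed in range(12):
            s = make_ideal_helix(HelixSpec(n_residues=24, noise_sd=sd, seed=seed))
            bs.append(sk.bending_angle(_ca(s, 1, 24)))
        bends.append(np.mean(bs))
    assert bends[0] < bends[1] < bends[2]


def test_bend_needs_three_windows():
    with pytest.raises(ValueError):
        sk.bending_angle(np.zeros((10, 3)), window=4)


def test_tilt_angles_exact():
    assert sk.tilt_angle(Z, Z) == pytest.approx(0.0, abs=1e-9)
    assert sk.tilt_angle([1.0, 0.0, 0.0], Z) == pytest.approx(90.0, abs=1e-9)
    tilted = rotation_about_axis([0, 1, 0], 25.0) @ Z
    assert sk.tilt_angle(tilted, Z) == pytest.approx(25.0, abs=1e-9)
    # folding: an axis at 155 deg from the normal reports 25 deg
    assert sk.tilt_angle(-tilted, Z) == pytest.approx(25.0, abs=1e-9)


def test_interhelical_angles_directed():
    assert sk.interhelical_angle(Z, Z) == pytest.approx(0.0, abs=1e-9)
    assert sk.interhelical_angle(Z, -Z) == pytest.approx(180.0, abs=1e-9)
    crossed = rotation_about_axis([1, 0, 0], 60.0) @ Z
    assert sk.interhelical_angle(Z, crossed) == pytest.approx(60.0, abs=1e-9)
    assert sk.interhelical_angle(crossed, Z) == pytest.approx(60.0, abs=1e-9)


def test_zero_vectors_rejected():
    with pytest.raises(ValueError):
        sk.tilt_angle(np.zeros(3), Z)
    with pytest.raises(ValueError):
        sk.interhelical_angle(Z, np.zeros(3))


def test_angles_invariant_under_joint_rigid_motion():
    """Tilt/crossing change only if the structure moves relative to the frame."""
    a = make_ideal_helix(HelixSpec(n_residues=20, axis=(0.3, 0.1, 1.0)))
    ax1, _ = sk.helix_axis(_ca(a, 1, 20))
    b = make_ideal_helix(HelixSpec(n_residues=20, axis=(1.0, 0.2, 0.8), origin=(12, 0, 0)))
    ax2, _ = sk.helix_axis(_ca(b, 1, 20))
    base_cross = sk.interhelical_angle(ax1, ax2)
    rot = rotation_about_axis([2, -1, 1], 77.0)
    a2 = a.transformed(rot, np.array([3.0, 4.0, 5.0]))
    b2 = b.transformed(rot, np.array([3.0, 4.0, 5.0]))
    ax1r, _ = sk.helix_axis(_ca(a2, 1, 20))
    ax2r, _ = sk.helix_axis(_ca(b2, 1, 20))
    assert sk.interhelical_angle(ax1r, ax2r) == pytest.approx(base_cross, abs=1e-9)
    # tilt against the co-rotated normal is likewise preserved
    assert sk.tilt_angle(ax1r, rot @ Z) == pytest.approx(sk.tilt_angle(ax1, Z), abs=1e-9)


def test_transformer_tables():
    helices = {
        "H1": DomainDefinition("H1", ((1, 20),)),
        "H2": DomainDefinition("H2", ((31, 50),)),
    }
    h1 = make_ideal_helix(HelixSpec(n_residues=20))
    import numpy as np

    from sercakit.synthetic import _build_atom_array, _helix_coords

    c2, r2, n2 = _helix_coords(HelixSpec(n_residues=20, axis=(1.0, 0.0, 1.0), origin=(15, 0, 0)))
    coords = np.vstack([h1.coord, c2])
    res_ids = np.concatenate([h1.atoms.res_id, r2 + 30])
    names = np.concatenate([h1.atoms.atom_name, n2])
    s = sk.Structure(id="pair", atoms=_build_atom_array(coords, res_ids, names), coord=coords)

    model = sk.TransmembraneGeometry(helices=helices, pairs=[("H1", "H2")]).fit()
    metrics = model.transform([s])
    assert set(metrics["helix"]) == {"H1", "H2"}
    h1_row = metrics[metrics["helix"] == "H1"].iloc[0]
    assert h1_row["helicity"] > 0.7
    assert h1_row["tilt_deg"] == pytest.approx(0.0, abs=1.0)
    h2_row = metrics[metrics["helix"] == "H2"].iloc[0]
    assert h2_row["tilt_deg"] == pytest.approx(45.0, abs=1.0)

    pairs = model.interhelical_angles([s])
    assert len(pairs) == 1
    assert pairs.iloc[0]["angle_deg"] == pytest.approx(45.0, abs=1.0)
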