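"""Voxel-shell contact detection vs brute-force definitional oracles."""

import numpy as np
import pytest

from organelle3d import (
    cell_contactome,
    contact_area,
    contact_sites,
    shell,
    surface_voxels,
)


from . import oracles

SP = (100.0, 10.0, 10.0)


def cube_pair(face=10, gap_axis_len=0):
    """Two 10x10x10 cubes sharing a full face (or separated)."""
    g = np.zeros((14, 26 + gap_axis_len, 14), dtype=bool)
    a = g.copy()
    b = g.copy()
    a[2:12, 2:12, 2:12] = True
    b[2:12, 12 + gap_axis_len: 22 + gap_axis_len, 2:12] = True
    return a, b


def test_cube_surface_enumeration():
    m = np.zeros((5, 5, 5), dtype=bool)
    m[1:4, 1:4, 1:4] = True
    assert int(surface_voxels(m).sum()) == 26  # all but the center


def test_single_voxel():
    m = np.zeros((3, 3, 3), dtype=bool)
    m[1, 1, 1] = True
    assert int(surface_voxels(m).sum()) == 1
    assert int(shell(m, 6).sum()) == 6
    assert int(shell(m, 26).sum()) == 26


def test_shell_clipped_at_boundary():
    m = np.zeros((3, 3, 3), dtype=bool)
    m[0, 0, 0] = True
    sh = shell(m, 6)
    assert int(sh.sum()) == 3  # three in-grid face neighbors, no wraparound


def test_worked_cube_fixture():
    """Full-face cube pair: 1 site, 100 overlap voxels, 0.01 um^2."""
    a, b = cube_pair()
    n, area = contact_area(a, b, SP)
    assert n == 100
    # 100 voxels x (10 nm x 10 nm) = 1e4 nm^2 = 1e-2 um^2
    assert area == pytest.approx(1e-2, rel=1e-12)
    sites = contact_sites(a, b, SP)
    assert len(sites) == 1
    assert sites[0].n_overlap == 100


def test_distant_masks_no_contact():
    a, b = cube_pair(gap_axis_len=3)
    assert contact_area(a, b, SP) == (0, 0.0)
    assert contact_sites(a, b, SP) == []


def test_one_voxel_gap_not_detected():
    a, b = cube_pair(gap_axis_len=1)
    n, _ = contact_area(a, b, SP)
    assert n == 0


def test_two_site_dumbbell():
    """Primary touching the secondary at two opposite ends -> 2 sites."""
    a = np.zeros((8, 30, 8), dtype=bool)
    b = a.copy()
    a[2:6, 2:28, 2:6] = True            # long bar
    b[2:6, 0:2, 2:6] = True             # cap at one end
    b[2:6, 28:30, 2:6] = True           # cap at the other
    sites = contact_sites(a, b, SP)
    assert len(sites) == 2
    assert sum(s.n_overlap for s in sites) == contact_area(a, b, SP)[0]


def test_monotonic_overlap_in_face_size():
    last = 0
    for w in (2, 4, 6, 10):
        g = np.zeros((14, 26, 14), dtype=bool)
        a, b = g.copy(), g.copy()
        a[2:12, 2:12, 2:12] = True
        b[2: 2 + w, 12:22, 2: 2 + w] = True
        n, _ = contact_area(a, b, SP)
        assert n > last
        last = n


def test_padding_invariance():
    a, b = cube_pair()
    n0, s0 = contact_area(a, b, SP), len(contact_sites(a, b, SP))
    ap = np.pad(a, 4)
    bp = np.pad(b, 4)
    assert contact_area(ap, bp, SP) == n0
    assert len(contact_sites(ap, bp, SP)) == s0


@pytest.mark.parametrize("connectivity", [6, 18, 26])
def test_shell_matches_brute_force(connectivity):
    rng = np.random.default_rng(42)
    for _ in range(12):
        m = oracles.random_blob(rng)
        assert oracles.mask_to_set(surface_voxels(m)) == \
            oracles.bf_surface_voxels(m)
        assert oracles.mask_to_set(shell(m, connectivity)) == \
            oracles.bf_shell(m, connectivity)


def test_contact_matches_brute_force_on_blob_pairs():
    rng = np.random.default_rng(7)
    for _ in range(15):
        a, b = oracles.adjacent_blob_pair(rng)
        n, _ = contact_area(a, b, SP)
        overlap = oracles.bf_overlap(a, b)
        assert n == len(overlap)
        sites = contact_sites(a, b, SP)
        bf = oracles.bf_sites(overlap)
        assert sorted(s.n_overlap for s in sites) == \
            sorted(len(c) for c in bf)


def test_area_uses_xy_pixel_area_only():
    a, b = cube_pair()
    n, area = contact_area(a, b, (100.0, 25.0, 40.0))
    assert area == pytest.approx(n * 25.0 * 40.0 / 1e6)


def test_contactome_matches_ground_truth(small_panel):
    """Detected partner sets equal the generator's designed partner sets,
    voxel-shell detection with default 6-connectivity."""
    for vol, gt in small_panel:
        table = cell_contactome(vol)
        for lbl, cls in table.instance_classes.items():
            detected = {table.instance_classes[p] for p in table.partners[lbl]}
            assert detected == set(gt.instances[lbl].category_partners), (
                f"{vol.cell_id} label {lbl} ({cls})"
            )


def test_contactome_site_additivity(small_cell_dark):
    vol, _ = small_cell_dark
    table = cell_contactome(vol)
    pair_df = table.pair_frame()
    site_df = table.sites_frame()
    for _, row in pair_df.iterrows():
        sub = site_df[site_df["pair"] == row["pair"]]
        assert row["total_area_um2"] == pytest.approx(sub["area_um2"].sum())
        assert row["n_sites"] == len(sub)


def test_contactome_alone_cell():
    """A frac_alone = 1 cell yields an empty contact table."""
    from .conftest import small_spec
    from organelle3d import generate_cell

    spec = small_spec(
        "dark", seed=9,
        frac_alone={"chloroplast": 1.0, "peroxisome": 1.0,
                    "mitochondrion": 1.0},
    )
    vol, gt = generate_cell(spec)
    assert not gt.pairs
    table = cell_contactome(vol)
    assert table.sites == []
    assert all(not v for v in table.partners.values())


def test_contactome_direction_convention(small_cell_dark):
    """Sites are reported with the alphabetically first class as primary."""
    vol, _ = small_cell_dark
    table = cell_contactome(vol)
    for s in table.sites:
        assert s.primary_class < s.secondary_class
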