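"""Generator contracts: determinism, counts, geometry, contact design."""

import numpy as np
import pytest

from organelle3d import generate_cell, generate_condition_panel
from organelle3d import synthetic as syn
from organelle3d.io import CHLOROPLAST, MITOCHONDRION, PEROXISOME, VACUOLE

from . import oracles
from .conftest import small_spec


def test_determinism_bit_identical():
    spec = small_spec("light", seed=21)
    v1, _ = generate_cell(spec)
    v2, _ = generate_cell(spec)
    assert np.array_equal(v1.labels, v2.labels)
    assert v1.class_map == v2.class_map


def test_counts_within_published_ranges(default_cell_dark):
    vol, gt = default_cell_dark
    for cls, (lo, hi) in syn.COUNT_RANGES["dark"].items():
        assert lo <= gt.count(cls) <= hi


def test_no_voxel_shared_and_truth_complete(small_panel):
    for vol, gt in small_panel:
        # instance labels partition the nonzero grid by construction;
        # every present label has exactly one truth record
        present = vol.present_labels()
        assert sorted(gt.instances) == present
        assert set(vol.class_map) == set(present)


def test_organelle_layout(default_cell_dark):
    """Chloroplasts peripheral, vacuole large, occupancy as in real cells."""
    vol, _ = default_cell_dark
    occ = syn.occupancy_fractions(vol)
    assert occ[CHLOROPLAST] + occ[VACUOLE] > 0.60
    assert occ[VACUOLE] > 0.25


def test_alone_spec_produces_no_contacts():
    spec = small_spec("dark", seed=2,
                      frac_alone={CHLOROPLAST: 1.0, PEROXISOME: 1.0,
                                  MITOCHONDRION: 1.0})
    _, gt = generate_cell(spec)
    assert not gt.pairs
    assert all(not t.category_partners for t in gt.instances.values()
               if t.organelle_class in (CHLOROPLAST, PEROXISOME,
                                        MITOCHONDRION))


def test_gap_zero_partners_face_adjacent(small_cell_dark):
    """Designed gap-0 pairs have at least one face-adjacent voxel pair
    (verified by brute-force neighbor scan)."""
    vol, gt = small_cell_dark
    pairs = [p for p in gt.pairs if p.contact]
    assert pairs, "design produced no contacts"
    for p in pairs[:8]:
        a = vol.mask(p.label_a)
        b = vol.mask(p.label_b)
        touching = False
        for v in map(tuple, np.argwhere(a)):
            for d in oracles.FACE:
                n = tuple(x + y for x, y in zip(v, d))
                if all(0 <= c < s for c, s in zip(n, b.shape)) and b[n]:
                    touching = True
                    break
            if touching:
                break
        assert touching, (p.label_a, p.label_b)


def test_gap_one_partners_beyond_shell_reach():
    spec = small_spec("dark", seed=4, contact_gap_vox=1)
    vol, gt = generate_cell(spec)
    designed = [p for p in gt.pairs if p.gap_vox == 1]
    assert designed, "no gap-1 pairs designed"
    assert all(not p.contact for p in designed)
    from organelle3d import cell_contactome

    table = cell_contactome(vol)
    assert table.sites == []


def test_alone_fraction_recovery_monte_carlo():
    """Across seeds, realized Alone fractions track the generating
    probability (binomial 99% CI on pooled counts)."""
    p = 0.35
    alone = total = 0
    for seed in range(8):
        spec = small_spec("light", seed=100 + seed,
                          frac_alone={CHLOROPLAST: 0.0, PEROXISOME: 0.1,
                                      MITOCHONDRION: p})
        _, gt = generate_cell(spec)
        ids = gt.labels_of_class(MITOCHONDRION)
        alone += sum(1 for i in ids if not gt.instances[i].category_partners)
        total += len(ids)
    half = 2.576 * np.sqrt(p * (1 - p) / total)
    assert abs(alone / total - p) <= half + 0.03  # +3% placement slack


def test_condition_panel_ids_and_sizes():
    from .conftest import SMALL_OVERRIDES

    panel = generate_condition_panel(3, "dark", seed=5, **SMALL_OVERRIDES)
    assert [v.cell_id for v, _ in panel] == ["D1", "D2", "D3"]
    vols = {v.cell_id: (v.labels > 0).sum() for v, _ in panel}
    assert len(set(vols.values())) == 3  # cell sizes jittered


def test_light_vs_dark_generator_effects():
    """Generator-level effect directions over a 5+5 small panel: larger
    peroxisomes and fewer branched mitochondria in the light."""
    per_vol = {"dark": [], "light": []}
    branches = {"dark": 0, "light": 0}
    for cond in ("dark", "light"):
        for seed in range(5):
            _, gt = generate_cell(small_spec(cond, seed=200 + seed))
            for lbl in gt.labels_of_class(PEROXISOME):
                per_vol[cond].append(gt.instances[lbl].shape["radius_nm"])
            for lbl in gt.labels_of_class(MITOCHONDRION):
                branches[cond] += bool(
                    gt.instances[lbl].shape.get("branched", False)
                )
    assert np.median(per_vol["light"]) > np.median(per_vol["dark"])
    assert branches["light"] <= branches["dark"]


def test_placement_error_reports_counts():
    spec = small_spec("dark", seed=0,
                      count_ranges={CHLOROPLAST: (40, 40),
                                    PEROXISOME: (4, 6),
                                    MITOCHONDRION: (8, 12)},
                      max_attempts=60)
    with pytest.raises(syn.PlacementError, match=r"\d+/40"):
        generate_cell(spec)


def test_invalid_specs_rejected():
    with pytest.raises(ValueError):
        syn.SynthSpec(condition="dusk")
    with pytest.raises(ValueError):
        syn.SynthSpec(contact_gap_vox=2)
    with pytest.raises(ValueError):
        syn.SynthSpec(frac_ternary=1.5)
    with pytest.raises(ValueError):
        generate_condition_panel(0, "dark", seed=1)
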