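import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mwcam.geometry import EPS0
from mwcam.phantoms import (
    ADIPOSE_TUMOR_SHAPE,
    FAT_SHELLS,
    GLANDS,
    GLAND_TUMOR_SHAPE,
    LABELS,
    SKIN_THICKNESS,
    TUMOR_SHAPES,
    PhantomConfig,
    SolidUnion,
    TissueDielectrics,
    build_phantom,
    contrast_slice,
    enumerate_configs,
    enumerate_heldout_configs,
    fits_inside,
    jitter_dielectrics,
    split_dataset,
    valid_cavity_pairs,
)


@pytest.mark.parametrize(
    "tumors,mirrors,rotations,expected",
    [(False, False, 1, 14), (True, False, 1, 56), (True, True, 16, 1792)],
)
def test_enumeration_counts(tumors, mirrors, rotations, expected):
    configs = enumerate_configs(tumors, mirrors, rotations)
    assert len(configs) == expected
    # deterministic, sorted enumeration
    again = enumerate_configs(tumors, mirrors, rotations)
    assert configs == again


def test_nesting_rule_matches_geometry():
    """The single combinatorial exclusion reflects actual solid nesting."""
    for fat_id, shell in FAT_SHELLS.items():
        inner = shell.shrunk(SKIN_THICKNESS)
        for gland_id, gland in GLANDS.items():
            nests = fits_inside(gland, inner, n=48)
            assert nests == ((fat_id, gland_id) != (1, 5))


def test_invalid_pair_rejected():
    with pytest.raises(ValueError, match="does not fit"):
        PhantomConfig(fat_id=1, gland_id=5)


def test_tumor_assignment_each_shape_once_per_cavity():
    """Each tumor shape pairs with a given cavity exactly once, and a
    two-tumor phantom never reuses a shape."""
    pairs = set()
    for fat_id, shape in ADIPOSE_TUMOR_SHAPE.items():
        key = ("fat", fat_id, shape)
        assert key not in pairs
        pairs.add(key)
    for gland_id, shape in GLAND_TUMOR_SHAPE.items():
        key = ("gland", gland_id, shape)
        assert key not in pairs
        pairs.add(key)
    for fat_id, gland_id in valid_cavity_pairs():
        assert ADIPOSE_TUMOR_SHAPE[fat_id] != GLAND_TUMOR_SHAPE[gland_id]


def test_tumor_diameters_within_bounds():
    for shape in TUMOR_SHAPES.values():
        parts = shape.parts if isinstance(shape, SolidUnion) else (shape,)
        lo = min(2 * min(p.semiaxes) for p in parts)
        pts = np.concatenate([p.surface_points(32) for p in parts])
        hi = max(pts[:, i].max() - pts[:, i].min() for i in range(3))
        assert 0.005 - 1e-9 <= hi <= 0.020 + 1e-9
        assert lo >= 0.005 - 1e-9


@settings(max_examples=200, deadline=None)
@given(seed=st.integers(min_value=0, max_value=10**6))
def test_jitter_bounded_and_water_fixed(seed):
    nominal = TissueDielectrics()
    jit = jitter_dielectrics(nominal, seed)
    for tissue, (eps_r, sigma) in jit.properties.items():
        eps0, sig0 = nominal.properties[tissue]
        if tissue == "water":
            assert (eps_r, sigma) == (eps0, sig0)
        else:
            assert abs(eps_r / eps0 - 1.0) <= 0.05
            assert abs(sigma / sig0 - 1.0) <= 0.05


def test_jitter_determinism_and_zero_amplitude(nominal):
    a = jitter_dielectrics(nominal, 42)
    b = jitter_dielectrics(nominal, 42)
    assert a.properties == b.properties
    ident = jitter_dielectrics(nominal, 42, amplitude=0.0)
    assert ident.properties == nominal.properties


def test_build_phantom_deterministic(nominal, grid, geometry):
    cfg = PhantomConfig(2, 2, tumor_case=4, rotation=5, mirror=True, jitter_seed=9)
    a = build_phantom(cfg, nominal, grid, geometry)
    b = build_phantom(cfg, nominal, grid, geometry)
    assert np.array_equal(a.labels, b.labels)
    assert np.array_equal(a.eps, b.eps)


def test_tumor_case_regions(nominal, grid, geometry):
    """Case 1 has no tumor voxels; case 4 places tumors in both the fatty
    and the glandular regions."""
    base = dict(fat_id=2, gland_id=3, jitter_seed=1)
    ph1 = build_phantom(PhantomConfig(tumor_case=1, **base), nominal, grid, geometry)
    ph4 = build_phantom(PhantomConfig(tumor_case=4, **base), nominal, grid, geometry)
    assert (ph1.labels == LABELS["tumor"]).sum() == 0
    tumor_vox = ph4.labels == LABELS["tumor"]
    assert tumor_vox.any()
    underlying = ph1.labels[tumor_vox]
    assert (underlying == LABELS["fat"]).any()
    assert (underlying == LABELS["glandular"]).any()


def test_mirror_is_reflection_not_rotation(nominal, grid, geometry):
    base = dict(fat_id=2, gland_id=4, tumor_case=2, jitter_seed=3)
    plain = build_phantom(PhantomConfig(**base), nominal, grid, geometry)
    mirr = build_phantom(PhantomConfig(mirror=True, **base), nominal, grid, geometry)
    # voxel-level reflection x -> -x on the overlapping symmetric subgrid
    assert np.array_equal(mirr.labels[1:], plain.labels[1:][::-1])
    # mirroring is not the half-turn rotation
    half = build_phantom(PhantomConfig(rotation=8, **base), nominal, grid, geometry)
    assert not np.array_equal(mirr.labels, half.labels)


def test_split_sizes_and_disjointness():
    configs = enumerate_configs(True, True, 16)
    train, val, test = split_dataset(configs, 0.8, shuffle_seed=7)
    assert (len(train), len(val), len(test)) == (1433, 359, 32)
    as_sets = [set(map(id, s)) for s in (train, val)]
    assert not (as_sets[0] & as_sets[1])
    assert all(c.family == "heldout" for c in test)
    # deterministic function of the seed
    train2, val2, _ = split_dataset(configs, 0.8, shuffle_seed=7)
    assert train == train2 and val == val2
    train3, _, _ = split_dataset(configs, 0.8, shuffle_seed=8)
    assert train != train3


def test_split_rejects_bad_fraction_and_heldout():
    configs = enumerate_configs(True, False, 1)
    with pytest.raises(ValueError):
        split_dataset(configs, 1.5)
    with pytest.raises(ValueError):
        split_dataset(configs + enumerate_heldout_configs(1), 0.8)


def test_heldout_count():
    assert len(enumerate_heldout_configs()) == 32


def test_contrast_slice_values(grid, geometry):
    nominal = TissueDielectrics()
    cfg = PhantomConfig(2, 3, tumor_case=4, jitter_seed=0)
    ph = build_phantom(cfg, nominal, grid, geometry)
    cm = contrast_slice(ph, 0.0)
    labels = ph.labels[:, grid.ny // 2, :]
    # water pixels carry exactly zero contrast
    assert np.all(cm.values[labels == LABELS["water"]] == 0)
    assert np.array_equal(cm.mask, labels != LABELS["water"])
    # nominal tumor pixel: Re(C) = 53 - 73 = -20
    tumor_px = labels == LABELS["tumor"]
    assert tumor_px.any()
    assert np.allclose(cm.values.real[tumor_px], 53.0 - 73.0)
    # fat pixel: hand evaluation of the contrast's imaginary part
    omega = 2 * np.pi * geometry.frequency
    eps_im = lambda sig: sig / (omega * EPS0)
    expect_im = -(eps_im(0.1) - eps_im(1.0))
    fat_px = labels == LABELS["fat"]
    assert np.allclose(cm.values.imag[fat_px], expect_im)
    assert expect_im > 0
    # real part never exceeds the water permittivity
    assert cm.values.real.max() <= 0


def test_contrast_slice_outside_grid(grid, geometry, nominal):
    ph = build_phantom(PhantomConfig(1, 1), nominal, grid, geometry)
    with pytest.raises(ValueError):
        contrast_slice(ph, 1.0)
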