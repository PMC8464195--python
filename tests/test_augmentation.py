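import numpy as np
import pytest

from honeychem.augmentation import AugmentationConfig, augment, channel_sd
from honeychem.features import GridSpec, assemble_features
from honeychem.labels import SampleLabel
from honeychem.profiles import SUGARS, SampleRecord, records_to_table

from conftest import matrix_from_values


def _single_row_matrix(grid_step=0.01):
    """One sample with three mid-scale bands per channel pair, for moment tests."""
    bands = {
        ("R254", 0.10): 0.55,
        ("R254", 0.30): 0.50,
        ("R254", 0.50): 0.60,
        ("R366", 0.15): 0.45,
        ("R366", 0.35): 0.50,
        ("R366", 0.55): 0.40,
    }
    rec = SampleRecord(SampleLabel("MAN"), {s: 100.0 for s in SUGARS}, bands)
    table = records_to_table([rec])
    return assemble_features(table, GridSpec(0.05, 0.60, grid_step))


def test_channel_sd_matches_two_pass_oracle(feature_matrix):
    sds = channel_sd(feature_matrix)
    assert set(sds) == {"R254", "R366", "TW_D", "R366_D"}
    for ch, sd in sds.items():
        block = feature_matrix.values[:, feature_matrix.organic_indices(ch)].ravel()
        mean = sum(block) / block.size
        var = sum((x - mean) ** 2 for x in block) / block.size
        assert sd == pytest.approx(var**0.5, rel=1e-12)


def test_channel_sd_closed_forms():
    m = matrix_from_values(np.array([[0.0, 1.0], [1.0, 0.0]]))
    assert channel_sd(m)["R254"] == pytest.approx(0.5)
    m2 = matrix_from_values(np.full((3, 4), 0.7))
    assert channel_sd(m2)["R254"] == pytest.approx(0.0, abs=1e-12)


def test_row_count_arithmetic(feature_matrix):
    for outer, inner, keep in [(2, 3, True), (2, 3, False), (0, 5, True)]:
        cfg = AugmentationConfig(outer_repeats=outer, inner_repeats=inner,
                                 keep_originals=keep, seed=1)
        out = augment(feature_matrix, cfg)
        expected = outer * inner * 68 + (68 if keep else 0)
        assert out.n_samples == expected
        # label marginals: every class has identical augmented multiplicity
        mult = outer * inner + (1 if keep else 0)
        from collections import Counter

        counts = Counter(out.labels)
        assert all(c == mult for c in counts.values())


def test_default_config_takes_68_rows_to_71468():
    cfg = AugmentationConfig()
    assert cfg.copies_per_row * 68 + 68 == 71468


def test_zero_noise_copies_equal_sources(feature_matrix):
    cfg = AugmentationConfig(
        rf_drift_bound=0.0,
        au_noise_multiplier=0.0,
        sugar_noise_fraction=0.0,
        outer_repeats=1,
        inner_repeats=2,
        seed=3,
    )
    out = augment(feature_matrix, cfg)
    for i in range(68):
        block = out.values[68 + 2 * i : 68 + 2 * (i + 1)]
        np.testing.assert_allclose(block, np.tile(feature_matrix.values[i], (2, 1)))


def test_outputs_are_non_negative(feature_matrix):
    out = augment(feature_matrix, AugmentationConfig(outer_repeats=2, inner_repeats=3, seed=9))
    assert out.values.min() >= 0.0


def test_determinism_under_seed(feature_matrix):
    cfg = AugmentationConfig(outer_repeats=1, inner_repeats=2, seed=11)
    a = augment(feature_matrix, cfg)
    b = augment(feature_matrix, cfg)
    np.testing.assert_array_equal(a.values, b.values)


def test_au_noise_moments_match_configured_multiplier():
    """10^5 perturbed band values per channel: the empirical noise SD must be
    within 2% of 1.25x the channel SD (drift disabled to isolate AU noise)."""
    matrix = _single_row_matrix()
    sds = channel_sd(matrix)
    copies = 34000  # 3 bands/channel -> ~1e5 draws per channel
    cfg = AugmentationConfig(
        rf_drift_bound=0.0,
        sugar_noise_fraction=0.0,
        outer_repeats=100,
        inner_repeats=copies // 100,
        keep_originals=False,
        seed=42,
    )
    out = augment(matrix, cfg)
    for ch in ("R254", "R366"):
        idx = matrix.organic_indices(ch)
        src = matrix.values[0, idx]
        band_cols = np.flatnonzero(src > 0)
        noise = out.values[:, idx][:, band_cols] - src[band_cols][None, :]
        expected = 1.25 * sds[ch]
        assert noise.std(ddof=0) == pytest.approx(expected, rel=0.02)


def test_rf_drift_bounded_and_uniform():
    """With AU noise off, drifted bands land within +/-0.0173 Rf of their
    origin and spread approximately uniformly over the reachable grid cells."""
    matrix = _single_row_matrix(grid_step=0.005)
    cfg = AugmentationConfig(
        au_noise_multiplier=0.0,
        sugar_noise_fraction=0.0,
        outer_repeats=100,
        inner_repeats=100,
        keep_originals=False,
        seed=7,
    )
    out = augment(matrix, cfg)
    idx = matrix.organic_indices("R254")
    grid = matrix.channel_grid("R254")
    src_cols = np.flatnonzero(matrix.values[0, idx] > 0)
    occupied = np.flatnonzero(out.values[:, idx].sum(axis=0) > 0)
    for o in occupied:
        assert np.min(np.abs(grid[src_cols] - grid[o])) <= 0.0173 + 0.0025 + 1e-9
    # uniformity: interior cells of one band's reachable window get similar mass
    col = src_cols[0]
    window = np.flatnonzero(np.abs(grid - grid[col]) <= 0.0150)
    counts = (out.values[:, idx][:, window] > 0).sum(axis=0)
    assert counts.min() > 0.8 * counts.max() - 1


def test_augment_validates_inputs(feature_matrix):
    with pytest.raises(ValueError):
        AugmentationConfig(rf_drift_bound=-0.1)
    with pytest.raises(ValueError):
        AugmentationConfig(outer_repeats=-1)
    sugars_only = feature_matrix.select("sugars")
    with pytest.raises(ValueError, match="channel"):
        augment(sugars_only, AugmentationConfig(outer_repeats=1, inner_repeats=1))
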