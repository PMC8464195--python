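"""Dataset augmentation emulating run-to-run HPTLC variability.

Each augmented copy of a sample perturbs

* every organic band's Rf position by a uniform draw within the drift bound
  (default +/-0.0173 Rf) before re-assignment to the nearest grid point
  (colliding bands keep the maximum),
* every band's AU by Gaussian noise whose standard deviation is a multiplier
  (default 1.25) times that imaging channel's standard deviation, computed
  over all of the channel's values across all samples, and
* every sugar quantity by Gaussian noise with standard deviation equal to a
  fraction (default 5 %) of the value,

with all perturbed values truncated at zero. With the default replication
counts (50 outer x 21 inner) and the originals kept, a 68-row matrix grows
to 50 x 21 x 68 + 68 = 71,468 rows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .features import FeatureMatrix


@dataclass(frozen=True)
class AugmentationConfig:
    rf_drift_bound: float = 0.0173
    au_noise_multiplier: float = 1.25
    sugar_noise_fraction: float = 0.05
    outer_repeats: int = 50
    inner_repeats: int = 21
    keep_originals: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.rf_drift_bound, self.au_noise_multiplier, self.sugar_noise_fraction) < 0:
            raise ValueError("noise bounds and fractions must be non-negative")
        if min(self.outer_repeats, self.inner_repeats) < 0:
            raise ValueError("repeat counts must be non-negative")

    @property
    def copies_per_row(self) -> int:
        return self.outer_repeats * self.inner_repeats


def channel_sd(matrix: FeatureMatrix) -> dict[str, float]:
    """Per-channel standard deviation over all AU cells of all samples."""
    channels = matrix.channels()
    if not channels:
        raise ValueError("matrix has no channel-tagged organic features")
    out = {}
    for ch in channels:
        block = matrix.values[:, matrix.organic_indices(ch)]
        if block.size < 2:
            raise ValueError(f"channel {ch} has fewer than 2 values")
        out[ch] = float(block.std(ddof=0))
    return out


def augment(matrix: FeatureMatrix, config: AugmentationConfig) -> FeatureMatrix:
    """Replicate every row with Rf drift, AU noise and sugar noise.

    Output rows are the originals (when kept) followed by
    ``outer_repeats * inner_repeats`` perturbed copies per source row, with
    labels copied from the source. Deterministic under the config seed. The
    result is returned unstandardised: noise moves values off the [0, 1]
    span, so re-standardise afterwards if a scaled matrix is needed.
    """
    sds = channel_sd(matrix)
    if matrix.sugar_indices().size == 0:
        raise ValueError("matrix has no sugar features")
    rng = np.random.default_rng(config.seed)
    n = matrix.n_samples
    copies = config.copies_per_row
    n_out = copies * n + (n if config.keep_originals else 0)

    out = np.zeros((n_out, matrix.n_features))
    labels = []
    offset = 0
    if config.keep_originals:
        out[:n] = matrix.values
        labels.extend(matrix.labels)
        offset = n

    sugar_idx = matrix.sugar_indices()
    chan_info = []
    for ch in matrix.channels():
        idx = matrix.organic_indices(ch)
        grid = matrix.channel_grid(ch)
        order = np.argsort(grid)
        chan_info.append((ch, idx[order], grid[order], config.au_noise_multiplier * sds[ch]))

    for i in range(n):
        rows = slice(offset + i * copies, offset + (i + 1) * copies)
        labels.extend([matrix.labels[i]] * copies)
        if copies == 0:
            continue
        for ch, idx, grid, sd in chan_info:
            vals = matrix.values[i, idx]
            bands = np.flatnonzero(vals > 0)
            if bands.size == 0:
                continue
            rf = grid[bands]
            drift = rng.uniform(-config.rf_drift_bound, config.rf_drift_bound, (copies, bands.size))
            new_rf = rf[None, :] + drift
            # nearest grid point, clipped to the grid ends
            pos = np.searchsorted(grid, new_rf)
            pos = np.clip(pos, 1, grid.size - 1)
            left_closer = new_rf - grid[pos - 1] < grid[pos] - new_rf
            pos = np.where(left_closer, pos - 1, pos)
            noisy = vals[bands][None, :] + sd * rng.standard_normal((copies, bands.size))
            noisy = np.maximum(noisy, 0.0)
            block = np.zeros((copies, grid.size))
            copy_rows = np.repeat(np.arange(copies), bands.size)
            np.maximum.at(block, (copy_rows, pos.ravel()), noisy.ravel())
            out[rows, idx] = block
        sugars = matrix.values[i, sugar_idx]
        z = rng.standard_normal((copies, sugar_idx.size))
        out[rows.start : rows.stop, sugar_idx] = np.maximum(
            sugars[None, :] * (1.0 + config.sugar_noise_fraction * z), 0.0
        )

    return FeatureMatrix(out, list(matrix.features), labels, standardised=False)
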