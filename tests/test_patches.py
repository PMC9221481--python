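"""Patch extraction against a flood-fill oracle, and the Sum5PaD / WFreq
summary statistics."""

import numpy as np
import pytest

from wavecoh.exceptions import ConfigError
from wavecoh.patches import (
    Patch, extract_patches, export_patch_table, read_patch_table, sum5pad,
    summarize, wfreq,
)

from conftest import map_from_mask


def flood_fill_components(mask, connectivity=4):
    """Exhaustive BFS component labelling (independent oracle)."""
    mask = np.asarray(mask, dtype=bool)
    seen = np.zeros_like(mask)
    offsets = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    if connectivity == 8:
        offsets += [(-1, -1), (-1, 1), (1, -1), (1, 1)]
    components = []
    for i in range(mask.shape[0]):
        for j in range(mask.shape[1]):
            if mask[i, j] and not seen[i, j]:
                queue, comp = [(i, j)], set()
                seen[i, j] = True
                while queue:
                    r, c = queue.pop()
                    comp.add((r, c))
                    for dr, dc in offsets:
                        rr, cc = r + dr, c + dc
                        if (0 <= rr < mask.shape[0] and 0 <= cc < mask.shape[1]
                                and mask[rr, cc] and not seen[rr, cc]):
                            seen[rr, cc] = True
                            queue.append((rr, cc))
                components.append(frozenset(comp))
    return set(components)


def make_patch(duration, f_lo, f_hi, t_min=0.0, rep=None):
    return Patch(
        id=0, t_min=t_min, t_max=t_min + duration, duration=duration,
        f_min=f_lo, f_max=f_hi, f_range=f_hi - f_lo, mean_coh=0.8,
        weighted_freq=rep if rep is not None else 0.5 * (f_lo + f_hi),
    )


class TestExtractPatches:
    def test_empty_mask_gives_no_patches(self):
        assert extract_patches(map_from_mask(np.zeros((5, 8), dtype=bool))) == []

    def test_rectangle_descriptors(self):
        # pixels spanning t in [2, 4) s at dt=0.2 and f rows 9..11 Hz
        mask = np.zeros((28, 30), dtype=bool)
        freqs = np.arange(3.0, 31.0)
        mask[6:9, 10:20] = True  # rows at 9, 10, 11 Hz
        patches = extract_patches(map_from_mask(mask, dt=0.2, freqs=freqs))
        assert len(patches) == 1
        p = patches[0]
        assert p.t_min == pytest.approx(2.0)
        assert p.t_max == pytest.approx(4.0)
        assert p.duration == pytest.approx(2.0)
        assert (p.f_min, p.f_max, p.f_range) == (9.0, 11.0, 2.0)

    def test_diagonal_blocks_split_under_4_connectivity(self):
        mask = np.zeros((6, 6), dtype=bool)
        mask[0:2, 0:2] = True
        mask[2:4, 2:4] = True  # touches only diagonally
        cmap = map_from_mask(mask)
        assert len(extract_patches(cmap, connectivity=4)) == 2
        assert len(extract_patches(cmap, connectivity=8)) == 1

    @pytest.mark.parametrize("seed", range(6))
    @pytest.mark.parametrize("connectivity", [4, 8])
    def test_labeling_matches_flood_fill_oracle(self, seed, connectivity):
        rng = np.random.default_rng(seed)
        shape = rng.integers(5, 31, size=2)
        mask = rng.random(shape) < 0.4
        patches = extract_patches(map_from_mask(mask), connectivity)
        got = {frozenset(map(tuple, p.pixels)) for p in patches}
        assert got == flood_fill_components(mask, connectivity)

    def test_pixel_counts_cover_mask(self, rng):
        mask = rng.random((20, 25)) < 0.3
        patches = extract_patches(map_from_mask(mask))
        assert sum(len(p.pixels) for p in patches) == mask.sum()

    def test_sorted_by_duration_then_start(self):
        mask = np.zeros((10, 30), dtype=bool)
        mask[1, 20:25] = True   # 5 px, late
        mask[5, 2:7] = True     # 5 px, early
        mask[8, 0:10] = True    # 10 px
        patches = extract_patches(map_from_mask(mask, dt=0.1))
        assert [round(p.duration, 3) for p in patches] == [1.0, 0.5, 0.5]
        assert patches[1].t_min < patches[2].t_min


class TestSum5PaD:
    def test_worked_example_75_percent(self):
        patches = [make_patch(d, 9, 11) for d in (5, 4, 3, 2, 1, 0.5)]
        assert sum5pad(patches, (8, 15), 20.0) == pytest.approx(75.0)

    def test_can_exceed_100_percent(self):
        patches = [make_patch(d, 9, 11) for d in (10, 9, 8, 7, 6)]
        assert sum5pad(patches, (8, 15), 20.0) == pytest.approx(200.0)

    def test_no_in_band_patches_gives_zero(self):
        patches = [make_patch(3, 20, 25)]
        assert sum5pad(patches, (8, 15), 20.0) == 0.0

    def test_band_edge_intersection_counts_fully(self):
        patches = [make_patch(4, 14, 18)]  # straddles the 15 Hz edge
        assert sum5pad(patches, (8, 15), 20.0) == pytest.approx(20.0)

    def test_band_clipping_counts_only_in_band_columns(self):
        # L-shaped patch: 10 columns at 20 Hz, only 4 of them also at 10 Hz
        mask = np.zeros((28, 30), dtype=bool)
        freqs = np.arange(3.0, 31.0)
        mask[17, 0:10] = True   # 20 Hz arm
        mask[7:18, 0:4] = True  # vertical arm reaching 10 Hz
        cmap = map_from_mask(mask, dt=0.5, freqs=freqs)
        patches = extract_patches(cmap)
        full = sum5pad(patches, (8, 15), cmap.total_duration_s)
        clipped = sum5pad(patches, (8, 15), cmap.total_duration_s,
                          clip_to_band=True, cmap=cmap)
        assert full == pytest.approx(100.0 * 5.0 / 15.0)
        assert clipped == pytest.approx(100.0 * 2.0 / 15.0)

    def test_non_positive_duration_rejected(self):
        with pytest.raises(ConfigError):
            sum5pad([], (8, 15), 0.0)

    def test_monotone_under_mask_growth(self, rng):
        mask = rng.random((15, 40)) < 0.2
        cmap = map_from_mask(mask, dt=0.1)
        base = sum5pad(extract_patches(cmap), (3, 30), cmap.total_duration_s)
        grown = mask.copy()
        grown[rng.random(mask.shape) < 0.15] = True
        cmap2 = map_from_mask(grown, dt=0.1)
        assert sum5pad(extract_patches(cmap2), (3, 30), cmap2.total_duration_s) >= base


class TestWFreq:
    def test_single_patch_midpoint(self):
        assert wfreq([make_patch(2, 9, 11)], (8, 15), method="midpoint") == pytest.approx(10.0)

    def test_duration_weighted_mean(self):
        patches = [make_patch(3, 8, 10, rep=9.0), make_patch(1, 12, 14, rep=13.0)]
        assert wfreq(patches, (8, 15)) == pytest.approx(10.0)

    def test_empty_band_undefined(self):
        assert wfreq([make_patch(2, 20, 25)], (8, 15)) is None

    def test_within_convex_hull_of_representatives(self, rng):
        patches = [
            make_patch(rng.uniform(0.5, 5), 8, 15, rep=rng.uniform(8, 15))
            for _ in range(7)
        ]
        reps = [np.clip(p.weighted_freq, 8, 15) for p in patches]
        value = wfreq(patches, (8, 15))
        assert min(reps) - 1e-9 <= value <= max(reps) + 1e-9


class TestSummarizeAndExport:
    def test_two_default_bands_give_two_summaries(self, rng):
        cmap = map_from_mask(rng.random((20, 30)) < 0.3)
        summaries = summarize(cmap)
        assert [s.band for s in summaries] == [(8.0, 15.0), (3.0, 25.0)]

    def test_empty_mask_summary(self):
        cmap = map_from_mask(np.zeros((20, 30), dtype=bool))
        s = summarize(cmap, ((8.0, 15.0),))[0]
        assert s.sum5pad_pct == 0.0 and s.wfreq_hz is None and s.n_patches == 0

    def test_band_outside_range_rejected(self, rng):
        cmap = map_from_mask(rng.random((20, 30)) < 0.3)
        with pytest.raises(ConfigError):
            summarize(cmap, ((20.0, 40.0),))

    def test_coupled_pair_wfreq_recovers_drive_frequency(self):
        from wavecoh.coherence import WaveletConfig, significant_coherence
        from wavecoh.synthetic import TrialSpec, make_trial_pair

        spec = TrialSpec(duration_s=10.0, fs_hz=250.0, coupling=0.9, seed=8)
        rec_a, rec_b = make_trial_pair(spec)
        cmap = significant_coherence(
            rec_a.channel("MMGtri"), rec_b.channel("MMGtri"), 250.0,
            WaveletConfig(n_surrogates=30, seed=5),
        )
        s = summarize(cmap, ((8.0, 15.0),))[0]
        assert 9.0 <= s.wfreq_hz <= 11.0

    def test_export_round_trip(self, tmp_path, rng):
        cmap = map_from_mask(rng.random((15, 25)) < 0.3, dt=0.1)
        patches = extract_patches(cmap)
        path = export_patch_table(cmap, patches, tmp_path / "patches.tsv")
        total, n, back = read_patch_table(path)
        assert total == pytest.approx(cmap.total_duration_s)
        assert n == len(patches)
        fields = ("id", "t_min", "t_max", "duration", "f_min", "f_max",
                  "f_range", "mean_coh", "weighted_freq")
        for p, q in zip(patches, back):
            for name in fields:
                assert getattr(q, name) == pytest.approx(getattr(p, name), rel=1e-9)

    def test_export_empty_patch_list(self, tmp_path):
        cmap = map_from_mask(np.zeros((5, 8), dtype=bool), dt=0.5)
        path = export_patch_table(cmap, [], tmp_path / "empty.tsv")
        total, n, back = read_patch_table(path)
        assert total == pytest.approx(4.0)
        assert n == 0 and back == []
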