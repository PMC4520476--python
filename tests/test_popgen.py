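import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from igamap.io import PoolCountTable, VariantFrequencyTable
from igamap.popgen import (
    fixation_blocks,
    fixation_windows,
    pooled_frequencies,
    sweep_scan,
    wc_fst,
    wc_fst_sites,
)
from igamap.simulate import SimConfig, simulate_pools, simulate_variant_table


def vtable(freqs, breed="gsd", pos=None):
    freqs = np.asarray(freqs, dtype=float)
    n = len(freqs)
    df = pd.DataFrame({
        "chrom": "28",
        "pos": np.arange(1, n + 1) * 100 if pos is None else pos,
        "ref": "A", "alt": "C",
        f"freq_{breed}": freqs, f"n_{breed}": 20,
    })
    return VariantFrequencyTable(df, [breed])


def wc_fst_oracle(p1, n1, p2, n2):
    """Independent transcription of the two-sample variance-component
    estimator (haploid samples, so the heterozygosity terms are zero)."""
    r = 2
    n_bar = (n1 + n2) / r
    n_c = (r * n_bar - (n1**2 + n2**2) / (r * n_bar)) / (r - 1)
    p_bar = (n1 * p1 + n2 * p2) / (r * n_bar)
    s_sq = (n1 * (p1 - p_bar) ** 2 + n2 * (p2 - p_bar) ** 2) / ((r - 1) * n_bar)
    a = (n_bar / n_c) * (s_sq - (1 / (n_bar - 1)) *
                         (p_bar * (1 - p_bar) - ((r - 1) / r) * s_sq))
    b = (n_bar / (n_bar - 1)) * (p_bar * (1 - p_bar) - ((r - 1) / r) * s_sq)
    return a / (a + b)


class TestFixationWindows:
    def test_21_variants_make_two_windows(self):
        vt = vtable(np.full(21, 0.5))
        windows = fixation_windows(vt, "gsd")
        assert len(windows) == 2
        assert (windows[0].first_variant, windows[0].last_variant) == (0, 10)
        assert (windows[1].first_variant, windows[1].last_variant) == (10, 20)

    def test_all_fixed_saturates(self):
        vt = vtable(np.ones(31))
        windows = fixation_windows(vt, "gsd")
        assert all(w.proportion_fixed == 1.0 for w in windows)

    def test_proportions_match_brute_force(self, rng):
        freqs = rng.choice([0.0, 1.0, 0.3, 0.7], size=51)
        vt = vtable(freqs)
        windows = fixation_windows(vt, "gsd")
        fixed = (freqs == 0) | (freqs == 1)
        for w in windows:
            brute = fixed[w.first_variant:w.last_variant + 1].mean()
            assert w.proportion_fixed == pytest.approx(brute)

    def test_windows_share_one_variant(self):
        vt = vtable(np.full(41, 0.5))
        windows = fixation_windows(vt, "gsd")
        for a, b in zip(windows, windows[1:]):
            assert a.last_variant == b.first_variant

    def test_fewer_variants_than_window_is_empty(self):
        assert fixation_windows(vtable(np.full(5, 0.5)), "gsd") == []

    def test_even_window_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            fixation_windows(vtable(np.full(21, 0.5)), "gsd", window_size=10)


class TestFixationBlocks:
    def test_no_fixed_window_no_block(self):
        vt = vtable(np.full(21, 0.5))
        assert fixation_blocks(fixation_windows(vt, "gsd"), vt, "gsd") == []

    def test_single_fixed_window_without_extension(self):
        freqs = np.full(31, 0.5)
        freqs[10:21] = 1.0  # exactly window 2 (variants 10..20)
        vt = vtable(freqs)
        blocks = fixation_blocks(fixation_windows(vt, "gsd"), vt, "gsd")
        assert len(blocks) == 1
        assert (blocks[0].first_variant, blocks[0].last_variant) == (10, 20)
        assert blocks[0].n_variants == 11

    def test_extension_capped_at_five(self):
        freqs = np.full(41, 0.5)
        freqs[2:30] = 1.0  # fixed run variants 2..29; window 10..20 fully fixed
        vt = vtable(freqs)
        blocks = fixation_blocks(fixation_windows(vt, "gsd"), vt, "gsd")
        assert len(blocks) == 1
        b = blocks[0]
        # merged windows span 10..30?  windows at starts 10 and 20: window 20
        # covers 20..30 which includes non-fixed variant 30 -> only window 1
        assert b.first_variant == 5 and b.last_variant == 25

    def test_planted_run_recovered_exactly(self):
        cfg = SimConfig(seed=5)
        start = 105  # window-grid compatible alignment (5 mod 10)
        vt, truth = simulate_variant_table(
            cfg, planted_blocks=[("gsd", start, start + 29)], n_variants=500)
        blocks = fixation_blocks(fixation_windows(vt, "gsd"), vt, "gsd")
        assert len(blocks) == 1
        assert (blocks[0].first_variant, blocks[0].last_variant) == (start, start + 29)
        assert blocks[0].n_variants == 30

    def test_rescan_of_block_is_idempotent(self):
        # a 26-variant fixed run: window grid + 5-variant extension tile it
        # exactly, so re-scanning the emitted block returns the block itself
        freqs = np.full(60, 0.5)
        freqs[5:31] = 1.0
        vt = vtable(freqs)
        blocks = fixation_blocks(fixation_windows(vt, "gsd"), vt, "gsd")
        assert len(blocks) == 1
        b = blocks[0]
        sub = VariantFrequencyTable(
            vt.table.iloc[b.first_variant:b.last_variant + 1].reset_index(drop=True),
            ["gsd"])
        sub_blocks = fixation_blocks(fixation_windows(sub, "gsd"), sub, "gsd")
        assert len(sub_blocks) == 1
        assert (sub_blocks[0].start, sub_blocks[0].end) == (b.start, b.end)


class TestPooledFrequencies:
    def test_ratios(self):
        df = pd.DataFrame({
            "chrom": "28", "pos": [1, 2],
            "ref_allele": "A", "alt_allele": "G",
            "w_ref": [10, 0], "w_alt": [10, 12],
            "d_ref": [5, 3], "d_alt": [15, 0],
        })
        out = pooled_frequencies(PoolCountTable(df, ["w", "d"]))
        np.testing.assert_allclose(out["w_freq"], [0.5, 1.0])
        np.testing.assert_allclose(out["d_freq"], [0.75, 0.0])
        assert out["usable"].all()

    def test_zero_depth_flagged(self):
        df = pd.DataFrame({
            "chrom": "28", "pos": [1],
            "ref_allele": "A", "alt_allele": "G",
            "w_ref": [0], "w_alt": [0], "d_ref": [5], "d_alt": [5],
        })
        out = pooled_frequencies(PoolCountTable(df, ["w", "d"]))
        assert np.isnan(out["w_freq"].iloc[0])
        assert not out["usable"].iloc[0]

    def test_summed_dog_pools_match_hand_sum(self):
        pools = [f"d{i}" for i in range(5)]
        data = {"chrom": "28", "pos": [1], "ref_allele": "A", "alt_allele": "G"}
        for i, p in enumerate(pools):
            data[f"{p}_ref"] = [i + 1]
            data[f"{p}_alt"] = [2 * i]
        t = PoolCountTable(pd.DataFrame(data), pools)
        total_ref = sum(t.counts(p)[0][0] for p in pools)
        total_alt = sum(t.counts(p)[1][0] for p in pools)
        assert total_ref == 1 + 2 + 3 + 4 + 5
        assert total_alt == 0 + 2 + 4 + 6 + 8
        assert total_alt / (total_ref + total_alt) == pytest.approx(20 / 35)


class TestWcFst:
    def test_no_differentiation_near_zero(self):
        theta = wc_fst(0.5, 50, 0.5, 50)
        assert -0.05 <= theta <= 0.05

    def test_fixed_difference_is_one(self):
        assert wc_fst(1.0, 50, 0.0, 50) == pytest.approx(1.0, abs=1e-6)

    def test_matches_independent_transcription(self, rng):
        for _ in range(10):
            p1, p2 = rng.uniform(0.05, 0.95, 2)
            n1, n2 = rng.integers(10, 100, 2)
            assert wc_fst(p1, n1, p2, n2) == pytest.approx(
                wc_fst_oracle(p1, n1, p2, n2), abs=1e-10)

    def test_vectorized_matches_scalar(self, rng):
        p1 = rng.uniform(0, 1, 20)
        p2 = rng.uniform(0, 1, 20)
        n1 = rng.integers(1, 80, 20).astype(float)
        n2 = rng.integers(1, 80, 20).astype(float)
        vec = wc_fst_sites(p1, n1, p2, n2)
        for j in range(20):
            scalar = wc_fst(p1[j], n1[j], p2[j], n2[j])
            if np.isnan(scalar):
                assert np.isnan(vec[j])
            else:
                assert vec[j] == pytest.approx(scalar, abs=1e-12)

    @settings(max_examples=40, deadline=None)
    @given(st.floats(0.01, 0.99), st.floats(0.01, 0.99),
           st.integers(5, 200), st.integers(5, 200))
    def test_symmetric_and_relabel_invariant(self, p1, p2, n1, n2):
        a = wc_fst(p1, n1, p2, n2)
        assert a == pytest.approx(wc_fst(p2, n2, p1, n1), abs=1e-12)
        assert a == pytest.approx(wc_fst(1 - p1, n1, 1 - p2, n2), abs=1e-12)

    def test_monomorphic_overall_is_nan(self):
        assert np.isnan(wc_fst(0.0, 50, 0.0, 50))
        assert np.isnan(wc_fst(0.5, 0, 0.5, 50))


class TestSweepScan:
    def _pools(self, seed=0, **kw):
        cfg = SimConfig(seed=seed)
        pools, _ = simulate_pools(cfg, (800_001, 900_000), 0.3, 0.9, 50, **kw)
        return pools

    def test_z_scores_standardized(self):
        df = sweep_scan(self._pools())
        assert df["z_fst"].mean() == pytest.approx(0.0, abs=1e-10)
        assert df["z_fst"].to_numpy().std() == pytest.approx(1.0, abs=1e-10)
        assert df["z_hp"].to_numpy().std() == pytest.approx(1.0, abs=1e-10)

    def test_window_below_min_segregating_dropped(self):
        # 9 segregating sites in the lone window -> nothing emitted -> error
        rng = np.random.default_rng(0)
        df = pd.DataFrame({
            "chrom": "28", "pos": np.arange(1, 10) * 1000,
            "ref_allele": "A", "alt_allele": "G",
            "wolf_ref": 25, "wolf_alt": 25, "dog_ref": 40, "dog_alt": 10,
        })
        with pytest.raises(ValueError, match="fewer than 2"):
            sweep_scan(PoolCountTable(df, ["wolf", "dog"]))

    def test_min_segregating_boundary(self):
        """A window with exactly 9 segregating sites is dropped, 10 kept."""
        rows = []
        for w, n_sites in ((0, 9), (2, 10), (4, 12)):  # non-overlapping windows
            start = w * 25_000
            for j in range(n_sites):
                rows.append({"chrom": "28", "pos": start + 1000 + j * 100,
                             "ref_allele": "A", "alt_allele": "G",
                             "wolf_ref": 20, "wolf_alt": 30,
                             "dog_ref": 35, "dog_alt": 15})
        pools = PoolCountTable(pd.DataFrame(rows), ["wolf", "dog"])
        df = sweep_scan(pools)
        assert df["n_segregating"].min() >= 10
        starts = set(df["start"])
        assert 1 not in starts           # 9-site window dropped
        assert {50_001, 100_001} <= starts

    def test_mean_fst_within_member_range(self):
        pools = self._pools(3)
        df = sweep_scan(pools)
        fa = pools.table["wolf_alt"] / (pools.table["wolf_ref"] + pools.table["wolf_alt"])
        assert ((df["mean_fst"] >= -0.2) & (df["mean_fst"] <= 1.0)).all()

    def test_hp_monotone_toward_fixation(self):
        """Pooled heterozygosity falls as dog frequencies approach 0 or 1."""
        def hp_for(alt_frac):
            alt = int(round(50 * alt_frac))
            rows = [{"chrom": "1", "pos": 1000 + j * 100,
                     "ref_allele": "A", "alt_allele": "G",
                     "wolf_ref": 25, "wolf_alt": 25,
                     "dog_ref": 50 - alt, "dog_alt": alt} for j in range(30)]
            rows += [{"chrom": "1", "pos": 60_000 + j * 100,
                      "ref_allele": "A", "alt_allele": "G",
                      "wolf_ref": 25, "wolf_alt": 25,
                      "dog_ref": 25, "dog_alt": 25} for j in range(30)]
            df = sweep_scan(PoolCountTable(pd.DataFrame(rows), ["wolf", "dog"]))
            return df.sort_values("start")["h_p"].iloc[0]
        hps = [hp_for(f) for f in (0.5, 0.3, 0.1, 0.02)]
        assert all(a > b for a, b in zip(hps, hps[1:]))

    def test_planted_sweep_is_global_extreme(self):
        pools = self._pools(1)
        df = sweep_scan(pools)
        top = df.loc[df["z_fst"].idxmax()]
        low = df.loc[df["z_hp"].idxmin()]
        assert top["start"] <= 900_000 and top["end"] >= 800_001
        assert low["start"] <= 900_000 and low["end"] >= 800_001
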