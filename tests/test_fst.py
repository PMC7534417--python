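"""Weir-Cockerham F_ST, d_i standardization, windowing, empirical tails."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import sweepscan as ss
from sweepscan.fst import (StandardizationConstants, pop_site_counts,
                           weir_cockerham_fst)


def wc84_oracle(p, n, h):
    """Formula-literal WC84 theta-hat for r populations (independent
    transcription: per-population allele frequencies p, diploid counts n,
    observed heterozygote frequencies h)."""
    r = len(p)
    nbar = sum(n) / r
    nc = (r * nbar - sum(ni ** 2 for ni in n) / (r * nbar)) / (r - 1)
    pbar = sum(ni * pi for ni, pi in zip(n, p)) / (r * nbar)
    s2 = sum(ni * (pi - pbar) ** 2 for ni, pi in zip(n, p)) / ((r - 1) * nbar)
    hbar = sum(ni * hi for ni, hi in zip(n, h)) / (r * nbar)
    a = (nbar / nc) * (s2 - (1 / (nbar - 1))
                       * (pbar * (1 - pbar) - ((r - 1) / r) * s2 - hbar / 4))
    b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - ((r - 1) / r) * s2
                               - ((2 * nbar - 1) / (4 * nbar)) * hbar)
    c = hbar / 2
    if a + b + c == 0:
        return math.nan
    return a / (a + b + c)


class TestSiteFst:
    def test_fixed_difference_is_exactly_one(self):
        assert ss.site_fst(20, 10, 0, 0, 10, 0) == 1.0

    def test_no_differentiation_is_nonpositive(self):
        v = ss.site_fst(10, 10, 4, 10, 10, 4)
        assert v <= 0.0

    def test_both_monomorphic_undefined(self):
        assert math.isnan(ss.site_fst(0, 10, 0, 0, 10, 0))

    def test_small_sample_marked_missing(self):
        assert math.isnan(ss.site_fst(1, 1, 1, 3, 10, 1))

    def test_matches_formula_literal_oracle(self, rng):
        for _ in range(1000):
            n1, n2 = int(rng.integers(2, 40)), int(rng.integers(2, 40))
            a1, a2 = int(rng.integers(0, 2 * n1 + 1)), int(rng.integers(0, 2 * n2 + 1))
            h1 = int(rng.integers(0, min(a1, 2 * n1 - a1) + 1))
            h2 = int(rng.integers(0, min(a2, 2 * n2 - a2) + 1))
            got = ss.site_fst(a1, n1, h1, a2, n2, h2)
            want = wc84_oracle([a1 / (2 * n1), a2 / (2 * n2)], [n1, n2],
                               [h1 / n1, h2 / n2])
            if math.isnan(want):
                assert math.isnan(got)
            else:
                assert got == pytest.approx(want, abs=1e-12)

    def test_fixture_counts(self, fixtures):
        n1, alt1, het1 = pop_site_counts(fixtures["fst_pop1"])
        n2, alt2, het2 = pop_site_counts(fixtures["fst_pop2"])
        got = weir_cockerham_fst(alt1, np.full(6, n1), het1,
                                 alt2, np.full(6, n2), het2)
        for j in range(6):
            want = wc84_oracle([alt1[j] / 20, alt2[j] / 20], [10, 10],
                               [het1[j] / 10, het2[j] / 10])
            if math.isnan(want):
                assert math.isnan(got[j])
            else:
                assert got[j] == pytest.approx(want, abs=1e-12)
        assert got[1] == 1.0            # fixed difference column
        assert math.isnan(got[3])       # monomorphic column


class TestDi:
    def _tracks(self, f1, f2):
        base = pd.DataFrame({"chrom": "1", "pos": np.arange(1, len(f1) + 1)})
        t1 = base.copy(); t1["fst"] = f1
        t2 = base.copy(); t2["fst"] = f2
        return {"ref1": t1, "ref2": t2}

    def test_worked_arithmetic_example(self):
        tracks = self._tracks([0.8], [0.6])
        consts = {"ref1": StandardizationConstants(0.2, 0.15, 10),
                  "ref2": StandardizationConstants(0.1, 0.12, 10)}
        di = ss.di_per_site(tracks, consts)
        assert di["di"].iloc[0] == pytest.approx(8.1667, abs=1e-4)

    def test_centering_identity(self):
        tracks = self._tracks([0.2, 0.2], [0.1, 0.1])
        consts = {"ref1": StandardizationConstants(0.2, 0.15, 2),
                  "ref2": StandardizationConstants(0.1, 0.12, 2)}
        assert np.allclose(ss.di_per_site(tracks, consts)["di"], 0.0)

    def test_standardized_addend_mean_zero_variance_one(self, rng):
        vals = rng.random(5000)
        track = pd.DataFrame({"chrom": "1", "pos": np.arange(1, 5001),
                              "fst": vals})
        c = ss.standardization_constants(track, autosomes=("1",))
        z = (vals - c.mean) / c.sd
        assert abs(z.mean()) < 1e-9
        assert abs(z.var() - 1.0) < 1e-6

    def test_missing_in_any_pair_missing_in_di(self):
        tracks = self._tracks([0.5, np.nan], [0.5, 0.5])
        consts = {"ref1": StandardizationConstants(0.2, 0.1, 2),
                  "ref2": StandardizationConstants(0.2, 0.1, 2)}
        di = ss.di_per_site(tracks, consts)["di"]
        assert np.isfinite(di.iloc[0]) and np.isnan(di.iloc[1])

    def test_degenerate_sd_is_hard_error(self):
        with pytest.raises(ValueError, match="sd"):
            StandardizationConstants(0.2, 0.0, 5)

    def test_constants_use_listed_autosomes_only(self, rng):
        track = pd.DataFrame({
            "chrom": ["1"] * 50 + ["X"] * 50,
            "pos": list(range(1, 51)) * 2,
            "fst": np.concatenate([rng.random(50) * 0.1,
                                   rng.random(50) * 0.9 + 0.1])})
        c_auto = ss.standardization_constants(track, autosomes=("1",))
        c_all = ss.standardization_constants(track, autosomes=("1", "X"))
        assert c_auto.n_sites == 50 and c_all.n_sites == 100
        assert c_auto.mean != c_all.mean


class TestWindowMean:
    def test_simple_mean_and_empty_window(self):
        grid = ss.make_windows({"1": 300}, 100)
        track = pd.DataFrame({"chrom": "1", "pos": [10, 20, 30],
                              "v": [1.0, 2.0, 3.0]})
        w = ss.window_mean(track, grid, "v", min_sites=1)
        assert w["value"].iloc[0] == 2.0
        assert np.isnan(w["value"].iloc[1]) and w["n_sites"].iloc[1] == 0

    def test_min_sites_flags_missing_not_zero(self):
        grid = ss.make_windows({"1": 100}, 100)
        track = pd.DataFrame({"chrom": "1", "pos": [10, 20], "v": [5.0, 7.0]})
        w = ss.window_mean(track, grid, "v", min_sites=10)
        assert np.isnan(w["value"].iloc[0]) and w["n_sites"].iloc[0] == 2

    def test_matches_bruteforce_windowing(self, rng):
        grid = ss.make_windows({"1": 5_000, "2": 3_000}, 700)
        rows = []
        for chrom, length in (("1", 5_000), ("2", 3_000)):
            pos = np.sort(rng.choice(np.arange(1, length + 1), 300,
                                     replace=False))
            vals = rng.normal(size=300)
            vals[rng.random(300) < 0.1] = np.nan
            rows.append(pd.DataFrame({"chrom": chrom, "pos": pos, "v": vals}))
        track = pd.concat(rows, ignore_index=True)
        w = ss.window_mean(track, grid, "v", min_sites=1)
        for i, win in grid.windows.iterrows():
            sel = track[(track["chrom"] == win["chrom"])
                        & (track["pos"] - 1 >= win["start"])
                        & (track["pos"] - 1 < win["end"])]
            vals = sel["v"].dropna()
            if len(vals) == 0:
                assert np.isnan(w["value"].iloc[i])
            else:
                assert w["value"].iloc[i] == pytest.approx(vals.mean())


class TestEmpiricalThreshold:
    @staticmethod
    def _wtrack(values):
        n = len(values)
        return pd.DataFrame({"chrom": "1", "start": np.arange(n) * 10,
                             "end": (np.arange(n) + 1) * 10, "value": values})

    def test_order_statistics_oracle_1_to_100(self):
        thr, flags = ss.empirical_threshold(self._wtrack(np.arange(1.0, 101.0)),
                                            tail=0.05)
        assert thr == 95.0
        assert sorted(np.flatnonzero(flags) + 1) == [96, 97, 98, 99, 100]

    def test_all_equal_flags_nothing(self):
        _, flags = ss.empirical_threshold(self._wtrack(np.full(50, 3.3)))
        assert flags.sum() == 0

    def test_half_tail_top_half(self):
        vals = np.concatenate([np.arange(1.0, 11.0), np.full(10, np.nan)])
        thr, flags = ss.empirical_threshold(self._wtrack(vals), tail=0.5)
        assert thr == 5.0
        assert sorted(np.flatnonzero(flags)) == [5, 6, 7, 8, 9]

    def test_too_few_windows_is_hard_error(self):
        with pytest.raises(ValueError, match="defined windows"):
            ss.empirical_threshold(self._wtrack(np.arange(10.0)))

    @given(st.lists(st.floats(-50, 50), min_size=25, max_size=120),
           st.sampled_from([0.05, 0.1, 0.25, 0.5]))
    def test_flagged_fraction_never_exceeds_tail(self, values, tail):
        _, flags = ss.empirical_threshold(self._wtrack(np.array(values)), tail)
        assert flags.sum() / len(values) <= tail + 1e-12
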