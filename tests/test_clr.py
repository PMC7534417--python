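"""Background SFS, sweep-distorted site probabilities, CLR maximization."""

import itertools
import math

import numpy as np
import pytest

import sweepscan as ss
from sweepscan.clr import (CLRTable, SiteFrequencySpectrum, clr_at,
                           estimate_background_sfs, project_spectrum,
                           sweep_kernel, sweep_site_prob, sweep_site_probs)


def toy_sfs(probs, folded=False):
    """Spectrum over classes 1..n-1 from an explicit probability list."""
    n = len(probs) + 1
    full = np.zeros(n + 1)
    full[1:n] = probs
    return SiteFrequencySpectrum(n, full, folded=folded)


def sweep_prob_oracle(j, n, alpha, d, probs):
    """Exhaustive summation over k swept lineages and ancestral
    configurations (independent of the package's kernel/projection code).

    probs: background over derived counts 1..n-1 (length n-1 list).
    """
    if alpha == 0.0:
        return probs[j - 1] if 1 <= j <= n - 1 else 0.0
    pc = math.exp(-alpha * d)
    total = 0.0
    for k in range(n + 1):
        w_k = math.comb(n, k) * pc ** k * (1 - pc) ** (n - k)
        m = n if k <= 1 else n - k + 1
        for jp in range(1, n):           # ancestral class at size n
            p_jp = probs[jp - 1]
            if p_jp == 0.0:
                continue
            for i in range(m + 1):       # hypergeometric projection to m
                hyp = (math.comb(jp, i) * math.comb(n - jp, m - i)
                       / math.comb(n, m)) if i <= jp and m - i <= n - jp else 0.0
                if hyp == 0.0:
                    continue
                if k <= 1:
                    j_out = {i: 1.0}
                else:
                    j_out = {}
                    if m > 0:
                        j_out[min(i - 1 + k, n)] = i / m
                        j_out[i] = j_out.get(i, 0.0) + (1 - i / m)
                total += w_k * p_jp * hyp * j_out.get(j, 0.0)
    return total


class TestBackgroundSfs:
    def test_counting_example(self):
        sfs = estimate_background_sfs(np.array([1, 1, 2]), 4)
        assert sfs.probs[1] == pytest.approx(2 / 3)
        assert sfs.probs[2] == pytest.approx(1 / 3)
        assert sfs.probs[3] == 0.0

    def test_smoothing_strictly_positive_and_normalized(self):
        sfs = estimate_background_sfs(np.array([1, 1, 2]), 6, smoothing=True)
        assert (sfs.probs[1:6] > 0).all()
        assert sfs.probs.sum() == pytest.approx(1.0, abs=1e-12)

    def test_zero_sites_is_hard_error(self):
        with pytest.raises(ValueError, match="zero sites"):
            estimate_background_sfs(np.array([], dtype=int), 4)

    def test_invariant_classes_only_when_enabled(self):
        with pytest.raises(ValueError):
            estimate_background_sfs(np.array([0, 1]), 4)
        sfs = estimate_background_sfs(np.array([0, 1, 4]), 4,
                                      include_invariant=True)
        assert sfs.probs[0] == pytest.approx(1 / 3)

    def test_neutral_simulation_close_to_1_over_j(self):
        """The unfolded neutral spectrum follows ~1/j; compare the pooled
        spectrum of ten neutral replicates to the normalized 1/j curve."""
        counts = []
        n = None
        for seed in range(10):
            res = ss.simulate(ss.SimParams(
                seed=seed, n_e=60, chrom_length=150_000, n_chromosomes=1,
                split_gens=1,
                sample_sizes={"focal": 10, "ref1": 2, "ref2": 2}))
            hap = res.population_genome("focal")["1"]
            n = hap.n_haplotypes
            dc = hap.alleles.sum(axis=0)
            counts.append(dc[(dc > 0) & (dc < n)])
        counts = np.concatenate(counts)
        sfs = estimate_background_sfs(counts, n)
        j = np.arange(1, n)
        expect = (1 / j) / (1 / j).sum()
        # Monte-Carlo agreement: compare low-frequency mass, generous band
        assert abs(sfs.probs[1] - expect[0]) < 0.08
        assert sfs.probs[1] > sfs.probs[2] > sfs.probs[4]

    def test_projection_sums_to_one_and_identity(self, rng):
        probs = np.zeros(9)
        probs[1:8] = rng.random(7)
        probs /= probs.sum()
        for m in range(1, 9):
            q = project_spectrum(probs, 8, m)
            assert q.sum() == pytest.approx(1.0, abs=1e-12)
        np.testing.assert_allclose(project_spectrum(probs, 8, 8), probs,
                                   atol=1e-12)


class TestSweepSiteProb:
    def test_alpha_zero_is_background(self):
        sfs = toy_sfs([0.5, 0.3, 0.2])
        for j in range(1, 4):
            assert sweep_site_prob(j, 4, 0.0, 123.0, sfs) == sfs.probs[j]

    def test_far_distance_reverts_to_background(self):
        sfs = toy_sfs([0.5, 0.3, 0.2])
        for j in range(1, 4):
            got = sweep_site_prob(j, 4, 1e-3, 1e9, sfs, renormalize=False)
            assert got == pytest.approx(sfs.probs[j], abs=1e-9)

    def test_exhaustive_enumeration_oracle_n4(self):
        probs = [0.5, 0.3, 0.2]
        sfs = toy_sfs(probs)
        alpha, d = 0.5, 1.0           # alpha * d = 0.5
        for j in range(5):
            want = sweep_prob_oracle(j, 4, alpha, d, probs)
            got = sweep_site_prob(j, 4, alpha, d, sfs, renormalize=False)
            assert got == pytest.approx(want, abs=1e-12)

    @pytest.mark.parametrize("n", [2, 3, 4, 5, 6])
    def test_full_class_set_sums_to_one_all_n(self, n, rng):
        probs = rng.random(n - 1)
        probs /= probs.sum()
        sfs = toy_sfs(list(probs))
        for ad in (0.0, 0.1, 0.7, 3.0, 30.0):
            P = sweep_site_probs(sfs, np.array([math.exp(-ad)]),
                                 renormalize=False)[0]
            assert P.sum() == pytest.approx(1.0, abs=1e-12)
            want = [sweep_prob_oracle(j, n, 1.0, ad, list(probs)) if ad > 0
                    else None for j in range(n + 1)]
            if ad > 0:
                np.testing.assert_allclose(P, want, atol=1e-12)

    def test_renormalized_mass_on_polymorphic_classes(self):
        sfs = toy_sfs([0.5, 0.3, 0.2])
        P = sweep_site_probs(sfs, np.array([0.7]), renormalize=True)[0]
        assert P[0] == 0.0 and P[4] == 0.0
        assert P.sum() == pytest.approx(1.0, abs=1e-12)


class TestClrAt:
    def _fixture(self):
        # 3 sites around x = 5000 with small counts, toy spectrum, n = 4
        positions = np.array([4000.0, 5200.0, 6000.0])
        counts = np.array([1, 3, 2])
        sfs = toy_sfs([0.55, 0.25, 0.2])
        grid = (1e-5, 1e-4, 1e-3, 1e-2, 1e-1)
        return positions, counts, sfs, grid

    def test_matches_bruteforce_grid_evaluation(self):
        positions, counts, sfs, grid = self._fixture()
        probs = [0.55, 0.25, 0.2]
        x = 5000.0
        ll0 = sum(math.log(probs[j - 1]) for j in counts)
        best, best_a = ll0, 0.0
        for a in grid:
            ll = 0.0
            for pos, j in zip(positions, counts):
                # oracle probabilities, renormalized to polymorphic classes
                p_all = [sweep_prob_oracle(jj, 4, a, abs(pos - x), probs)
                         for jj in range(5)]
                poly = sum(p_all[1:4])
                ll += math.log(p_all[j] / poly)
            if ll > best:
                best, best_a = ll, a
        want_clr = 2 * (best - ll0)
        got_clr, got_a = clr_at(x, positions, counts, sfs, alpha_grid=grid,
                                flank=200_000)
        assert got_clr == pytest.approx(want_clr, abs=1e-10)
        assert got_a == best_a

    def test_null_maximum_gives_exact_zero(self):
        # counts drawn exactly at the background mode far away: alpha = 0 wins
        positions = np.array([1e6, 1.1e6])
        counts = np.array([1, 1])
        sfs = toy_sfs([0.9, 0.05, 0.05])
        clr, alpha = clr_at(0.0, positions, counts, sfs,
                            alpha_grid=(1e-6, 1e-5), flank=10_000_000)
        assert clr == 0.0 and alpha == 0.0

    def test_empty_flank_is_missing(self):
        positions = np.array([4000.0])
        clr, alpha = clr_at(1e7, positions, np.array([1]),
                            toy_sfs([0.5, 0.3, 0.2]), flank=1000)
        assert math.isnan(clr) and math.isnan(alpha)

    def test_grid_refinement_monotone_on_nested_grids(self):
        positions, counts, sfs, _ = self._fixture()
        coarse = (1e-4, 1e-2)
        fine = (1e-5, 1e-4, 1e-3, 1e-2, 1e-1)
        clr_c, _ = clr_at(5000.0, positions, counts, sfs, alpha_grid=coarse)
        clr_f, _ = clr_at(5000.0, positions, counts, sfs, alpha_grid=fine)
        assert clr_f >= clr_c - 1e-12

    def test_table_interpolation_tracks_exact_values(self):
        positions, counts, sfs, grid = self._fixture()
        table = CLRTable(sfs)
        d = np.abs(positions - 5000.0)
        for a in grid:
            exact = np.log([sweep_site_prob(j, 4, a, dd, sfs)
                            for j, dd in zip(counts, d)]).sum()
            approx = table.log_prob(a * d, counts).sum()
            assert approx == pytest.approx(exact, abs=1e-4)


class TestClrScan:
    @pytest.fixture(scope="class")
    def scanned(self):
        res = ss.simulate(ss.SimParams(
            seed=17, n_e=60, chrom_length=250_000, n_chromosomes=2,
            split_gens=60, sample_sizes={"focal": 10, "ref1": 4, "ref2": 4}))
        genome = res.population_genome("focal")
        grid = ss.make_windows({"1": 250_000, "2": 250_000}, 10_000)
        return ss.clr_scan(genome, grid, grid_step=1_000, flank=50_000)

    def test_grid_point_count(self, scanned):
        per_chrom = scanned.grid.groupby("chrom").size()
        assert (per_chrom == 250).all()

    def test_clr_nonnegative_everywhere(self, scanned):
        vals = scanned.grid["clr"].dropna()
        assert (vals >= 0).all()

    def test_window_max_reduction(self, scanned):
        g = scanned.grid
        w = scanned.window
        row = w.iloc[3]
        sel = g[(g["chrom"] == row["chrom"]) & (g["pos"] - 1 >= row["start"])
                & (g["pos"] - 1 < row["end"])]["clr"].dropna()
        assert row["value"] == pytest.approx(sel.max())

    def test_flagged_fraction_at_most_tail(self, scanned):
        defined = np.isfinite(scanned.window["value"]).sum()
        assert scanned.flags.sum() <= 0.05 * defined + 1e-9
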