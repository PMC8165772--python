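"""Window construction, diversity estimators, Tajima's D and FST.

Oracles: msprime/tskit for theta-pi, S and Tajima's D on a simulated tree
sequence; an independently coded scalar Weir-Cockerham (1984) per-site
implementation for windowed FST; hand-computed values for the small cases.
"""
from __future__ import annotations

import math

import numpy as np
import pytest

from conftest import make_gm
from ducksweep import (
    PopulationMap,
    WindowSpec,
    compute_window_stats,
    log2_pi_ratio,
    make_windows,
    population_allele_counts,
    tajima_constants,
    window_diversity,
    window_fst,
)


class TestMakeWindows:
    @pytest.mark.parametrize(
        "length,expected",
        [
            (100_000, [(1, 40_000), (20_001, 60_000), (40_001, 80_000), (60_001, 100_000)]),
            (40_000, [(1, 40_000)]),
            (50_000, [(1, 40_000), (20_001, 50_000)]),
        ],
    )
    def test_enumeration(self, length, expected):
        w = make_windows({"chr1": length}, WindowSpec(40_000, 20_000))
        assert list(zip(w["start"], w["end"])) == expected

    def test_invalid_spec(self):
        with pytest.raises(ValueError):
            WindowSpec(40_000, 0)
        with pytest.raises(ValueError):
            WindowSpec(40_000, 50_000)

    def test_windows_sorted_and_multi_chrom(self):
        w = make_windows({"chr2": 45_000, "chr1": 45_000}, WindowSpec(40_000, 20_000))
        assert w.groupby("chrom").size().to_dict() == {"chr1": 2, "chr2": 2}


def _counts_from_dosages(pos, dosages, pop="P"):
    gm = make_gm(pos, dosages)
    popmap = PopulationMap({s: pop for s in gm.samples})
    return population_allele_counts(gm, popmap)


class TestWindowDiversity:
    def test_no_variation(self):
        counts = _counts_from_dosages([10], [[0, 0]])
        S, pi, tw, d = window_diversity(counts, ("chr1", 1, 1000), "P")
        assert (S, pi, tw) == (0, 0.0, 0.0)
        assert math.isnan(d)

    def test_two_chromosomes_pairwise_differences(self):
        # one diploid sample = 2 chromosomes; 3 het sites in a 1000-bp window
        counts = _counts_from_dosages([10, 20, 30], [[1], [1], [1]])
        S, pi, tw, d = window_diversity(counts, ("chr1", 1, 1000), "P")
        assert S == 3
        assert pi == pytest.approx(3 / 1000)

    def test_watterson_harmonic_normalisation(self):
        # n=4 chromosomes, S=5 segregating sites in a 5-bp window:
        # theta_W = S / (a1 * L) with a1 = 1 + 1/2 + 1/3 = 11/6
        dosages = [[1, 0], [0, 1], [1, 1], [2, 1], [0, 1]]
        counts = _counts_from_dosages([1, 2, 3, 4, 5], dosages)
        S, pi, tw, d = window_diversity(counts, ("chr1", 1, 5), "P")
        assert S == 5
        assert tw == pytest.approx(5 / ((11 / 6) * 5))

    def test_tajima_constants_a1(self):
        a1, e1, e2 = tajima_constants(4)
        assert a1 == pytest.approx(11 / 6)

    def test_matches_tskit_on_simulated_tree_sequence(self):
        msprime = pytest.importorskip("msprime")
        ts = msprime.sim_ancestry(
            samples=10, population_size=1000, sequence_length=100_000, random_seed=3
        )
        ts = msprime.sim_mutations(
            ts, rate=5e-7, random_seed=4, model=msprime.BinaryMutationModel()
        )
        G = ts.genotype_matrix()
        pos = ts.tables.sites.position.astype(int) + 1
        assert len(np.unique(pos)) == len(pos)
        dosages = (G[:, 0::2] + G[:, 1::2]).astype(np.int8)
        counts = _counts_from_dosages(pos, dosages)
        S, pi, tw, d = window_diversity(counts, ("chr1", 1, 100_000), "P")
        a1 = sum(1 / i for i in range(1, 20))
        assert pi == pytest.approx(ts.diversity(), abs=1e-6)
        assert d == pytest.approx(ts.Tajimas_D(), abs=1e-6)
        assert S == int(ts.segregating_sites(span_normalise=False))
        assert tw == pytest.approx(S / (a1 * 100_000), abs=1e-6)

    def test_invariant_to_sample_order_and_allele_swap(self, two_pop_random_gm):
        gm, popmap = two_pop_random_gm
        counts = population_allele_counts(gm, popmap)
        ref = window_diversity(counts, ("chr1", 1, 100_000), "A")

        perm = np.random.default_rng(1).permutation(gm.n_samples)
        gm_perm = make_gm(
            gm.sites["pos"], gm.dosages[:, perm], samples=[gm.samples[i] for i in perm]
        )
        counts_perm = population_allele_counts(gm_perm, popmap)
        assert window_diversity(counts_perm, ("chr1", 1, 100_000), "A") == pytest.approx(ref, nan_ok=True)

        swapped = np.where(gm.dosages == -1, -1, 2 - gm.dosages).astype(np.int8)
        counts_swap = population_allele_counts(
            make_gm(gm.sites["pos"], swapped, samples=gm.samples), popmap
        )
        got = window_diversity(counts_swap, ("chr1", 1, 100_000), "A")
        assert got[:3] == pytest.approx(ref[:3])

    def test_additivity_of_disjoint_site_sets(self, two_pop_random_gm):
        gm, popmap = two_pop_random_gm
        counts = population_allele_counts(gm, popmap)
        lo_pos = int(np.median(gm.sites["pos"]))
        S_all, pi_all, _, _ = window_diversity(counts, ("chr1", 1, 100_000), "A")
        S1, pi1, _, _ = window_diversity(counts, ("chr1", 1, lo_pos), "A")
        S2, pi2, _, _ = window_diversity(counts, ("chr1", lo_pos + 1, 100_000), "A")
        assert S_all == S1 + S2
        # sum of per-site pi is additive; per-bp values rescale by length
        assert pi_all * 100_000 == pytest.approx(pi1 * lo_pos + pi2 * (100_000 - lo_pos))


def _wc_fst_reference(dos_a: np.ndarray, dos_b: np.ndarray) -> float:
    """Scalar ratio-of-sums Weir & Cockerham (1984) FST, transcribed
    independently from the published two-allele equations (r populations,
    here r=2), using observed heterozygote frequencies."""
    num = 0.0
    den = 0.0
    for site in range(dos_a.shape[0]):
        va = [d for d in dos_a[site] if d >= 0]
        vb = [d for d in dos_b[site] if d >= 0]
        n_i = [len(va), len(vb)]
        if min(n_i) < 1 or sum(n_i) <= 2:
            continue
        p_i = [sum(va) / (2 * len(va)), sum(vb) / (2 * len(vb))]
        h_i = [
            sum(1 for d in va if d == 1) / len(va),
            sum(1 for d in vb if d == 1) / len(vb),
        ]
        r = 2
        nbar = sum(n_i) / r
        nc = (r * nbar - sum(n**2 for n in n_i) / (r * nbar)) / (r - 1)
        pbar = sum(n * p for n, p in zip(n_i, p_i)) / (r * nbar)
        s2 = sum(n * (p - pbar) ** 2 for n, p in zip(n_i, p_i)) / ((r - 1) * nbar)
        hbar = sum(n * h for n, h in zip(n_i, h_i)) / (r * nbar)
        a = (
            nbar
            / nc
            * (s2 - 1 / (nbar - 1) * (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4))
        )
        b = nbar / (nbar - 1) * (
            pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2
        num += a
        den += a + b + c
    return num / den if den else math.nan


class TestFst:
    def _two_pop_counts(self, dosages_a, dosages_b, pos=None):
        dos_a = np.asarray(dosages_a, dtype=np.int8)
        dos_b = np.asarray(dosages_b, dtype=np.int8)
        if pos is None:
            pos = np.arange(1, dos_a.shape[0] + 1) * 10
        n_a = dos_a.shape[1]
        samples = [f"a{i}" for i in range(n_a)] + [f"b{i}" for i in range(dos_b.shape[1])]
        gm = make_gm(pos, np.hstack([dos_a, dos_b]), samples=samples)
        popmap = PopulationMap(
            {s: ("A" if s.startswith("a") else "B") for s in samples}
        )
        return population_allele_counts(gm, popmap)

    @pytest.mark.parametrize("estimator", ["weir_cockerham", "hudson"])
    def test_fixed_difference_is_one(self, estimator):
        counts = self._two_pop_counts([[2, 2, 2]], [[0, 0, 0]])
        assert window_fst(counts, ("chr1", 1, 100), "A", "B", estimator) == pytest.approx(1.0)

    def test_identical_populations_hudson_nonpositive(self):
        d = [[0, 1, 2], [1, 1, 0], [2, 0, 1]]
        counts = self._two_pop_counts(d, d)
        assert window_fst(counts, ("chr1", 1, 100), "A", "B", "hudson") <= 0

    def test_monomorphic_window_is_missing(self):
        counts = self._two_pop_counts([[0, 0, 0]], [[0, 0, 0]])
        assert math.isnan(window_fst(counts, ("chr1", 1, 100), "A", "B"))

    def test_unknown_estimator(self):
        counts = self._two_pop_counts([[2, 2, 2]], [[0, 0, 0]])
        with pytest.raises(ValueError, match="estimator"):
            window_fst(counts, ("chr1", 1, 100), "A", "B", "nei")

    def test_weir_cockerham_matches_scalar_reference(self, rng):
        dos_a = rng.integers(0, 3, size=(60, 6)).astype(np.int8)
        dos_b = rng.integers(0, 3, size=(60, 8)).astype(np.int8)
        dos_a[rng.random(dos_a.shape) < 0.08] = -1
        dos_b[rng.random(dos_b.shape) < 0.08] = -1
        counts = self._two_pop_counts(dos_a, dos_b)
        got = window_fst(counts, ("chr1", 1, 10_000), "A", "B", "weir_cockerham")
        assert got == pytest.approx(_wc_fst_reference(dos_a, dos_b), abs=1e-9)


class TestLog2Ratio:
    @pytest.mark.parametrize(
        "num,den,expected", [(2e-4, 1e-4, 1.0), (3e-4, 3e-4, 0.0)]
    )
    def test_values(self, num, den, expected):
        assert log2_pi_ratio(num, den) == pytest.approx(expected)

    def test_zero_denominator_is_missing(self):
        assert math.isnan(log2_pi_ratio(2e-4, 0.0))
        assert math.isnan(log2_pi_ratio(0.0, 2e-4))


class TestComputeWindowStats:
    def test_columns_and_pair_orientation(self, split_panel):
        params, gm, popmap, counts = split_panel
        windows = make_windows(gm.chrom_lengths, WindowSpec(40_000, 20_000))
        stats = compute_window_stats(counts, windows, pairs=[("wild", "domestic")])
        for col in (
            "n_snps",
            "pi_wild",
            "thetaw_domestic",
            "tajd_wild",
            "fst_wild_domestic",
            "log2ratio_wild_domestic",
        ):
            assert col in stats.columns
        assert len(stats) == len(windows)
        assert (stats["fst_wild_domestic"].dropna() <= 1.0).all()
        assert (stats["pi_wild"] >= 0).all() and (stats["thetaw_wild"].dropna() >= 0).all()

    def test_windowed_fst_agrees_with_single_window_api(self, split_panel):
        params, gm, popmap, counts = split_panel
        windows = make_windows(gm.chrom_lengths, WindowSpec(40_000, 20_000)).head(10)
        stats = compute_window_stats(counts, windows, pairs=[("wild", "domestic")])
        for row in stats.itertuples():
            single = window_fst(
                counts, (row.chrom, row.start, row.end), "wild", "domestic"
            )
            assert row.fst_wild_domestic == pytest.approx(single, nan_ok=True)
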