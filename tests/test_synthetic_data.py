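"""Coalescent generator: expectations, sweep signatures, determinism."""
from __future__ import annotations

import numpy as np
import pytest

from ducksweep import (
    CoalescentParams,
    SweepSpec,
    default_sweep_spec,
    mutate_genealogy,
    simulate_dataset,
    simulate_genealogy,
    simulate_genotype_matrix,
)
from ducksweep.synthetic_data import LocusSaturatedError


def _single_deme(ne, n_dip, **kw):
    return CoalescentParams(
        ne=ne, samples_per_pop=(n_dip,), model="single_deme", chrom_length=40_000, **kw
    )


class TestGenealogy:
    def test_pairwise_tmrca_expectation(self):
        # n=2 chromosomes: E[TMRCA] = 2*Ne, SD = 2*Ne
        ne = 500.0
        rng = np.random.default_rng(1)
        params = _single_deme(ne, 1)
        t = np.array(
            [simulate_genealogy(params, rng).tmrca for _ in range(5000)]
        )
        se = t.std(ddof=1) / np.sqrt(len(t))
        assert abs(t.mean() - 2 * ne) <= 3 * se

    def test_total_branch_length_expectation(self):
        # k lineages: E[total length] = 4*Ne * sum_{i=1}^{k-1} 1/i
        ne, k_dip = 500.0, 5
        rng = np.random.default_rng(2)
        params = _single_deme(ne, k_dip)
        totals = np.array(
            [simulate_genealogy(params, rng).total_branch_length for _ in range(3000)]
        )
        a1 = sum(1.0 / i for i in range(1, 2 * k_dip))
        se = totals.std(ddof=1) / np.sqrt(len(totals))
        assert abs(totals.mean() - 4 * ne * a1) <= 3 * se

    def test_split_model_tmrca_bounded_below_by_split_time(self):
        params = CoalescentParams(
            ne=100.0,
            samples_per_pop=(1, 1),
            model="split",
            split_time=10_000.0,
            chrom_length=40_000,
        )
        rng = np.random.default_rng(3)
        for _ in range(200):
            assert simulate_genealogy(params, rng).tmrca >= 10_000.0

    def test_island_model_coalesces_and_requires_migration(self):
        params = CoalescentParams(
            ne=100.0,
            samples_per_pop=(3, 3),
            model="island",
            migration_rate=1e-3,
            chrom_length=40_000,
        )
        rng = np.random.default_rng(4)
        tree = simulate_genealogy(params, rng)
        assert tree.root is not None and tree.tmrca > 0
        with pytest.raises(ValueError, match="migration"):
            CoalescentParams(
                ne=100.0, samples_per_pop=(3, 3), model="island", chrom_length=40_000
            )

    def test_star_genealogy_pairwise_time_is_tau(self):
        params = CoalescentParams(
            ne=1_000.0,
            samples_per_pop=(2, 3),
            model="split",
            split_time=5_000.0,
            chrom_length=40_000,
        )
        rng = np.random.default_rng(5)
        tree = simulate_genealogy(params, rng, sweep_tau=50.0, sweep_deme=1)
        # the 6 swept-deme chromosomes (leaves 4..9) share a parent at time tau
        masks = tree.leaf_masks()
        star_nodes = [
            n
            for n in range(tree.n_leaves, len(tree.times))
            if tree.times[n] == 50.0 and masks[n, 4:].all() and not masks[n, :4].any()
        ]
        assert len(star_nodes) == 1


class TestMutations:
    def test_zero_rate_gives_no_sites(self):
        params = _single_deme(500.0, 5, mu=0.0)
        rng = np.random.default_rng(6)
        tree = simulate_genealogy(params, rng)
        pos, haps = mutate_genealogy(tree, 0.0, 40_000, rng)
        assert len(pos) == 0

    def test_watterson_expectation_of_segregating_sites(self):
        # E[S] = theta * L * a1(n) per locus
        ne, mu, L = 2_000.0, 5e-8, 40_000
        params = _single_deme(ne, 10, mu=mu)
        rng = np.random.default_rng(7)
        s = []
        for _ in range(400):
            tree = simulate_genealogy(params, rng)
            pos, _ = mutate_genealogy(tree, mu, L, rng)
            s.append(len(pos))
        s = np.array(s, dtype=float)
        a1 = sum(1.0 / i for i in range(1, 20))
        expect = 4 * ne * mu * L * a1
        se = s.std(ddof=1) / np.sqrt(len(s))
        assert abs(s.mean() - expect) <= 3 * se

    def test_pairwise_diversity_expectation(self):
        # E[pi per bp] = 4*Ne*mu
        ne, mu, L = 2_000.0, 5e-8, 40_000
        params = _single_deme(ne, 10, mu=mu)
        rng = np.random.default_rng(8)
        pis = []
        for _ in range(300):
            tree = simulate_genealogy(params, rng)
            _, haps = mutate_genealogy(tree, mu, L, rng)
            n = haps.shape[1]
            freq = haps.sum(axis=1)
            pis.append((2 * freq * (n - freq) / (n * (n - 1))).sum() / L)
        pis = np.array(pis)
        se = pis.std(ddof=1) / np.sqrt(len(pis))
        assert abs(pis.mean() - 4 * ne * mu) <= 3 * se

    def test_positions_unique_and_in_range(self):
        params = _single_deme(5_000.0, 10, mu=1e-6)
        rng = np.random.default_rng(9)
        tree = simulate_genealogy(params, rng)
        pos, haps = mutate_genealogy(tree, 1e-6, 1_000, rng)
        assert len(np.unique(pos)) == len(pos)
        assert pos.min() >= 1 and pos.max() <= 1_000
        # infinite sites: every column polymorphic at the chromosome level
        assert ((haps.sum(axis=1) > 0) & (haps.sum(axis=1) < haps.shape[1])).all()

    def test_saturation_error(self):
        params = _single_deme(5_000.0, 10, mu=1.0)
        rng = np.random.default_rng(10)
        tree = simulate_genealogy(params, rng)
        with pytest.raises(LocusSaturatedError):
            mutate_genealogy(tree, 1.0, 100, rng)


class TestDataset:
    def test_tau_zero_swept_windows_monomorphic_in_swept_deme(self):
        params = CoalescentParams(
            ne=5_000.0,
            mu=1e-7,
            samples_per_pop=(4, 4),
            model="split",
            split_time=10_000.0,
            chrom_length=200_000,
            seed=11,
        )
        sweep = SweepSpec(intervals=((1, 80_000),), tau=0.0)
        gm, popmap, truth, _ = simulate_genotype_matrix(params, sweep=sweep)
        dom = gm.sample_indices(popmap.samples_for("domestic"))
        in_sweep = gm.sites["pos"] <= 80_000
        d = gm.dosages[in_sweep.to_numpy()][:, dom]
        # all domestic samples identical at every swept site
        assert (d == d[:, :1]).all()
        assert truth["swept"].tolist() == [True, True, False, False, False]

    def test_swept_windows_lose_diversity(self):
        params = CoalescentParams(
            ne=5_000.0,
            mu=1e-7,
            samples_per_pop=(6, 6),
            model="split",
            split_time=2_000.0,
            chrom_length=400_000,
            seed=12,
        )
        sweep = default_sweep_spec(params, n_regions=2, region_windows=2, tau=100.0)
        gm, popmap, truth, _ = simulate_genotype_matrix(params, sweep=sweep)
        from ducksweep import population_allele_counts, window_diversity

        counts = population_allele_counts(gm, popmap)
        swept_pi, neutral_pi = [], []
        for r in truth.itertuples():
            _, pi, _, _ = window_diversity(counts, (r.chrom, r.start, r.end), "domestic")
            (swept_pi if r.swept else neutral_pi).append(pi)
        assert np.mean(swept_pi) < 0.25 * np.mean(neutral_pi)

    def test_sweep_interval_outside_chromosome_rejected(self):
        params = CoalescentParams(ne=100.0, samples_per_pop=(2, 2), chrom_length=40_000)
        with pytest.raises(ValueError, match="outside"):
            simulate_genotype_matrix(
                params, sweep=SweepSpec(intervals=((1, 80_000),), tau=10.0)
            )

    def test_same_seed_byte_identical_vcf(self, tmp_path):
        params = CoalescentParams(
            ne=2_000.0, mu=1e-7, samples_per_pop=(3, 3), chrom_length=120_000, seed=13
        )
        ds1 = simulate_dataset(params, tmp_path / "a")
        ds2 = simulate_dataset(params, tmp_path / "b")
        assert ds1.vcf.read_bytes() == ds2.vcf.read_bytes()
        assert ds1.fasta.read_bytes() == ds2.fasta.read_bytes()
        assert ds1.truth.read_bytes() == ds2.truth.read_bytes()

    def test_file_bundle_mutually_consistent(self, tmp_path):
        from ducksweep import PopulationMap, load_bed12, read_vcf
        from ducksweep.annotate import ReferenceGenome

        params = CoalescentParams(
            ne=2_000.0, mu=1e-7, samples_per_pop=(3, 3), chrom_length=120_000, seed=14
        )
        ds = simulate_dataset(params, tmp_path)
        popmap = PopulationMap.from_tsv(ds.popmap)
        gm = read_vcf(ds.vcf, popmap)
        assert set(gm.samples) == set(popmap.samples)
        assert gm.chrom_lengths == {"chr1": 120_000}
        ref = ReferenceGenome.from_fasta(ds.fasta)
        assert ref.lengths() == {"chr1": 120_000}
        # VCF REF alleles match the FASTA
        for r in gm.sites.head(50).itertuples():
            assert ref.base(r.chrom, r.pos) == r.ref
        genes = load_bed12(ds.genes_bed)
        assert all(g.cds_length % 3 == 0 for g in genes)
        assert all(g.tx_end <= 120_000 for g in genes)

    def test_contaminated_sites_fail_filters(self):
        from ducksweep import apply_site_filters

        params = CoalescentParams(
            ne=5_000.0, mu=1e-7, samples_per_pop=(4, 4), chrom_length=200_000, seed=15
        )
        gm, *_ = simulate_genotype_matrix(params, contaminate=0.3)
        kept = apply_site_filters(gm)
        frac = kept.n_sites / gm.n_sites
        assert 0.6 <= frac <= 0.8
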