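"""Coalescent panels: genealogies, mutation placement, MAF conditioning."""

import numpy as np
import pytest
import tskit

from epiqtl.coalsim import (
    ResampleNeeded,
    SimConfig,
    assemble_diploids,
    place_conditioned_mutation,
    place_mutations,
    simulate_genealogies,
    simulate_panel,
)


def _single_tree(n_individuals, seed):
    cfg = SimConfig(
        n_individuals=n_individuals, n_chromosomes=2, markers_per_chromosome=1,
        qtl_positions=((0, 0), (1, 0)), genealogy_seed=seed,
    )
    return simulate_genealogies(cfg)[0].first()


class TestGenealogies:
    def test_no_recombination_gives_single_tree(self):
        cfg = SimConfig(
            n_individuals=20, n_chromosomes=2, markers_per_chromosome=30,
            rho_adjacent=0.0, qtl_positions=((0, 5), (1, 5)), genealogy_seed=3,
        )
        for ts in simulate_genealogies(cfg):
            assert ts.num_trees == 1

    def test_tmrca_matches_neutral_expectation(self):
        # E[T_MRCA] = 2(1 - 1/2n) coalescent units for 2n lineages
        n = 25
        heights = []
        for seed in range(1, 401):
            tree = _single_tree(n, seed)
            heights.append(tree.time(tree.root))
        expected = 2 * (1 - 1 / (2 * n))
        se = np.std(heights, ddof=1) / np.sqrt(len(heights))
        assert abs(np.mean(heights) - expected) <= 3 * se

    def test_deterministic_in_seed(self):
        cfg = SimConfig(n_individuals=15, genealogy_seed=7, mutation_seed=8)
        a = simulate_genealogies(cfg)
        b = simulate_genealogies(cfg)
        for ta, tb in zip(a, b):
            assert ta.tables.equals(tb.tables, ignore_provenance=True)

    def test_genealogy_constant_across_mutation_seeds(self):
        # the variance-reduction design: same genealogy seed, new mutations
        base = dict(n_individuals=30, n_chromosomes=2, markers_per_chromosome=10,
                    qtl_positions=((0, 3), (1, 3)), genealogy_seed=21)
        p1 = simulate_panel(SimConfig(mutation_seed=1, **base))
        p2 = simulate_panel(SimConfig(mutation_seed=2, **base))
        assert not np.array_equal(p1.haplotypes, p2.haplotypes)
        g1 = simulate_genealogies(SimConfig(mutation_seed=1, **base))
        g2 = simulate_genealogies(SimConfig(mutation_seed=2, **base))
        for ta, tb in zip(g1, g2):
            assert ta.tables.equals(tb.tables, ignore_provenance=True)

    def test_more_recombination_more_marginal_trees(self):
        means = []
        for rho in (0.0, 0.05, 0.5):
            counts = []
            for seed in range(5):
                cfg = SimConfig(
                    n_individuals=20, n_chromosomes=2, markers_per_chromosome=25,
                    rho_adjacent=rho, qtl_positions=((0, 5), (1, 5)),
                    genealogy_seed=100 + seed,
                )
                ts = simulate_genealogies(cfg)[0]
                counts.append(len({ts.at(p).index for p in range(25)}))
            means.append(np.mean(counts))
        assert means[0] == 1.0
        assert means[0] < means[1] < means[2]


class TestMutationPlacement:
    def test_every_column_polymorphic(self, small_panel):
        freqs = small_panel.haplotypes.mean(axis=0)
        assert ((freqs > 0) & (freqs < 1)).all()

    def test_leaf_branch_gives_singleton(self):
        from epiqtl.coalsim import _mutate_on_node

        tree = _single_tree(10, seed=5)
        ts = tree.tree_sequence
        leaf = next(iter(ts.samples()))
        col = _mutate_on_node(tree, int(leaf), ts.num_samples)
        assert col.sum() == 1 and col[leaf] == 1

    def test_site_frequency_spectrum_matches_branch_length_oracle(self):
        # the derived-allele-count distribution of single placed mutations
        # must match the exact per-tree branch-length probabilities (clade-
        # size-k branch length / total length, averaged over trees); it also
        # tracks the 1/k neutral spectrum, exactly only in expectation over
        # branch lengths, so the 1/k check is a looser shape bound
        from scipy import stats

        n, reps = 10, 2000
        counts = np.zeros(2 * n)
        exact = np.zeros(2 * n)
        for seed in range(1, reps + 1):
            tree = _single_tree(n, seed)
            rng = np.random.default_rng(10_000 + seed)
            col = place_mutations(tree.tree_sequence, [0], rng)
            counts[int(col.sum())] += 1
            total = tree.total_branch_length
            for u in tree.nodes():
                if tree.parent(u) != tskit.NULL:
                    exact[tree.num_samples(u)] += tree.branch_length(u) / total
        expected = exact / exact.sum() * reps
        mask = expected >= 5
        chi2 = ((counts[mask] - expected[mask]) ** 2 / expected[mask]).sum()
        assert stats.chi2.sf(chi2, mask.sum() - 1) > 0.01
        # neutral-spectrum shape: observed frequencies of the first classes
        # stay within 25% of the normalized 1/k law
        ks = np.arange(1, 2 * n)
        harmonic = (1 / ks) / (1 / ks).sum()
        obs_freq = counts[1:] / reps
        assert np.abs(obs_freq[:5] / harmonic[:5] - 1).max() < 0.25

    def test_unlinked_columns_nearly_uncorrelated(self):
        # markers on different chromosomes: E[r^2] ~ 1/2n
        n = 50
        r2 = []
        for seed in range(1, 201):
            cfg = SimConfig(
                n_individuals=n, n_chromosomes=2, markers_per_chromosome=1,
                qtl_positions=((0, 0), (1, 0)), maf_window=(0.05, 0.5),
                genealogy_seed=seed, mutation_seed=seed,
            )
            H = simulate_panel(cfg, markers=None).haplotypes.astype(float)
            if H[:, 0].std() > 0 and H[:, 1].std() > 0:
                r2.append(np.corrcoef(H[:, 0], H[:, 1])[0, 1] ** 2)
        mean = np.mean(r2)
        se = np.std(r2, ddof=1) / np.sqrt(len(r2))
        assert abs(mean - 1 / (2 * n)) <= 3 * se


class TestConditionedPlacement:
    @pytest.mark.parametrize(
        "window,lo_count,hi_count", [((0.2, 0.3), 40, 60), ((0.01, 0.10), 2, 20)]
    )
    def test_minor_allele_count_inside_window(self, window, lo_count, hi_count):
        n = 100
        rng = np.random.default_rng(0)
        tree = _single_tree(n, seed=42)
        col = place_conditioned_mutation(tree, window, rng)
        mac = min(col.sum(), 2 * n - col.sum())
        assert lo_count <= mac <= hi_count

    def test_distribution_spans_window(self):
        n, window = 60, (0.2, 0.3)
        mafs = []
        for seed in range(1, 201):
            tree = _single_tree(n, seed)
            rng = np.random.default_rng(seed)
            try:
                col = place_conditioned_mutation(tree, window, rng)
            except ResampleNeeded:
                continue
            # integer minor-allele count avoids float round-off at the edges
            k = int(col.sum())
            mafs.append(min(k, 2 * n - k) / (2 * n))
        mafs = np.array(mafs)
        assert len(mafs) > 150
        assert ((mafs >= window[0]) & (mafs <= window[1])).all()
        assert np.unique(np.round(mafs, 6)).size > 3  # not a point mass

    def test_impossible_window_raises(self):
        # with 2n = 4 leaves the attainable MAFs are {0.25, 0.5} only
        tree = _single_tree(2, seed=9)
        with pytest.raises(ResampleNeeded):
            place_conditioned_mutation(tree, (0.26, 0.49), np.random.default_rng(0))

    def test_panel_qtl_maf_always_in_window(self, small_panel, small_config):
        low, high = small_config.maf_window
        mafs = small_panel.minor_allele_freqs()[list(small_panel.qtl_cols)]
        assert ((mafs >= low) & (mafs <= high)).all()


class TestDiploidAssembly:
    def test_allele_sums(self):
        H = np.array([[0, 0, 1], [0, 1, 1], [1, 0, 0], [1, 1, 1]], dtype=np.uint8)
        from epiqtl.coalsim import HaplotypePanel

        panel = HaplotypePanel(
            haplotypes=H,
            marker_chrom=np.zeros(3, dtype=np.int64),
            marker_pos=np.arange(3, dtype=np.int64),
            qtl_cols=(),
        )
        G = assemble_diploids(panel)
        np.testing.assert_array_equal(G.genotypes, [[0, 1, 2], [2, 1, 1]])
        np.testing.assert_array_equal(
            G.genotypes.sum(axis=0), H.sum(axis=0)
        )

    def test_odd_haplotypes_rejected(self):
        from epiqtl.coalsim import HaplotypePanel

        panel = HaplotypePanel(
            haplotypes=np.zeros((3, 2), dtype=np.uint8),
            marker_chrom=np.zeros(2, dtype=np.int64),
            marker_pos=np.arange(2, dtype=np.int64),
            qtl_cols=(),
        )
        with pytest.raises(ValueError, match="odd"):
            assemble_diploids(panel)

    def test_default_genome_shape(self, small_config, small_genotypes):
        assert small_genotypes.genotypes.shape == (60, 60)
        assert len(small_genotypes.qtl_cols) == 2


class TestReproducibility:
    def test_identical_seeds_identical_panels(self):
        cfg = SimConfig(n_individuals=25, n_chromosomes=2, markers_per_chromosome=15,
                        qtl_positions=((0, 7), (1, 7)), genealogy_seed=5, mutation_seed=6)
        p1 = simulate_panel(cfg)
        p2 = simulate_panel(cfg)
        np.testing.assert_array_equal(p1.haplotypes, p2.haplotypes)

    def test_config_validation(self):
        with pytest.raises(ValueError, match="distinct chromosomes"):
            SimConfig(n_individuals=10, qtl_positions=((0, 4), (0, 8)))
        with pytest.raises(ValueError, match="maf_window"):
            SimConfig(n_individuals=10, maf_window=(0.3, 0.2))
        with pytest.raises(ValueError, match="outside"):
            SimConfig(n_individuals=10, qtl_positions=((0, 49), (9, 49)))

    def test_config_dict_round_trip(self):
        cfg = SimConfig(n_individuals=40, maf_window=(0.01, 0.1), genealogy_seed=2)
        assert SimConfig.from_dict(cfg.to_dict()) == cfg
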