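"""Normalization, variable-gene selection and t-type mapping."""

import numpy as np
import pytest

from patchseq.synthetic import AtlasSpec, generate_expression_bundle
from patchseq.transcriptomics import (ExpressionBundle, GeneSelectionParams,
                                      assign_ttypes, bootstrap_confidence,
                                      build_centroids, consensus_assignment,
                                      dropout_curve_stats, map_cell,
                                      normalize_expression, round1_qc,
                                      select_variable_genes)


# --------------------------------------------------------------------------
# Normalization
# --------------------------------------------------------------------------

class TestNormalize:
    def test_length_normalized_sum(self):
        b = ExpressionBundle(
            genes=np.array(["g1"]), exon_counts=np.array([[10]]),
            intron_counts=np.array([[5]]),
            exonic_length_kb=np.array([2.0]),
            intronic_length_kb=np.array([5.0]))
        # 10/2 + 5/(5 + 1e-6) + 1 = 7 (to guard precision)
        assert normalize_expression(b)[0, 0] == pytest.approx(np.log2(7.0),
                                                              abs=1e-6)

    def test_zero_counts_give_zero(self):
        b = ExpressionBundle(
            genes=np.array(["g1"]), exon_counts=np.array([[0]]),
            intron_counts=np.array([[0]]),
            exonic_length_kb=np.array([2.0]),
            intronic_length_kb=np.array([5.0]))
        assert normalize_expression(b)[0, 0] == 0.0

    def test_zero_intronic_length_guard(self):
        b = ExpressionBundle(
            genes=np.array(["g1"]), exon_counts=np.array([[4]]),
            intron_counts=np.array([[0]]),
            exonic_length_kb=np.array([1.0]),
            intronic_length_kb=np.array([0.0]))
        assert np.isfinite(normalize_expression(b)[0, 0])

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ExpressionBundle(genes=np.array(["g1"]),
                             exon_counts=np.array([[-1]]),
                             intron_counts=np.array([[0]]))

    def test_umi_passthrough(self):
        b = ExpressionBundle(genes=np.array(["g1"]),
                             exon_counts=np.array([[3]]), platform="UMI")
        assert normalize_expression(b)[0, 0] == pytest.approx(2.0)


# --------------------------------------------------------------------------
# Variable-gene selection
# --------------------------------------------------------------------------

def _nb_counts(n_genes, n_cells, seed, log_mean=3.0, log_sd=1.5):
    rng = np.random.default_rng(seed)
    mu = rng.lognormal(log_mean, log_sd, n_genes)
    p = 2.0 / (2.0 + mu[:, None])
    return rng.negative_binomial(2, p, size=(n_genes, n_cells))


class TestGeneSelection:
    def test_min_cells_rule_excludes_gene(self):
        counts = np.zeros((2, 20), dtype=int)
        counts[0, :9] = 40    # >= c_min in only 9 cells -> excluded
        counts[1, :15] = 40
        eligible, _, _ = dropout_curve_stats(
            counts, GeneSelectionParams(target_n=1))
        assert not eligible[0] and eligible[1]

    def test_exact_target_on_continuous_cloud(self):
        counts = _nb_counts(2000, 500, seed=0)
        params = GeneSelectionParams(target_n=500)
        sel = select_variable_genes(counts, params)
        assert len(sel) == 500

    def test_selection_matches_critical_offset_oracle(self):
        """Brute-force oracle: the selected set must be exactly the genes
        with the largest critical offsets b_g = ln(tau - margin) - slope*mu."""
        counts = _nb_counts(1500, 400, seed=1)
        params = GeneSelectionParams(target_n=300)
        sel = select_variable_genes(counts, params)
        eligible, mu, tau = dropout_curve_stats(counts, params)
        b_g = np.full(counts.shape[0], -np.inf)
        ok = eligible & (tau > params.margin)
        b_g[ok] = np.log(tau[ok] - params.margin) - params.slope * mu[ok]
        oracle = set(np.argsort(-b_g)[:300])
        assert set(sel) == oracle

    def test_selected_count_monotone_in_offset(self):
        counts = _nb_counts(800, 300, seed=2)
        params = GeneSelectionParams(target_n=100)
        eligible, mu, tau = dropout_curve_stats(counts, params)
        ok = eligible & (tau > params.margin)
        ns = []
        for b in np.linspace(-10, 10, 41):
            sel = tau[ok] > np.exp(params.slope * mu[ok] + b) + params.margin
            ns.append(int(sel.sum()))
        assert all(a >= b for a, b in zip(ns, ns[1:]))

    def test_target_exceeding_eligible_returns_all(self):
        counts = _nb_counts(50, 200, seed=3)
        params = GeneSelectionParams(target_n=5000)
        with pytest.warns(UserWarning):
            sel = select_variable_genes(counts, params)
        eligible, _, tau = dropout_curve_stats(counts, params)
        assert len(sel) == int((eligible & (tau > params.margin)).sum())


# --------------------------------------------------------------------------
# Centroids and mapping
# --------------------------------------------------------------------------

class TestCentroidsAndMapping:
    def test_single_cell_centroid_equals_cell(self):
        log_e = np.random.default_rng(0).normal(size=(10, 2))
        cents = build_centroids(log_e, np.array(["a", "b"]), ["a", "b"])
        assert np.allclose(cents[0], log_e[:, 0])

    def test_duplicate_cells_share_centroid(self):
        x = np.random.default_rng(0).normal(size=10)
        log_e = np.stack([x, x], axis=1)
        cents = build_centroids(log_e, np.array(["a", "a"]), ["a"])
        assert np.allclose(cents[0], x)

    def test_planted_centroids_recovered(self):
        spec = AtlasSpec(n_types=5, n_genes=300, n_cells_per_type=200, seed=0)
        atlases, _, _ = generate_expression_bundle(spec, n_query_cells=1)
        atlas = atlases[0]
        cents = build_centroids(atlas.log_expression(), atlas.cell_types,
                                atlas.type_names)
        planted = spec.build_centroids()
        # correlation with own planted centroid beats all others
        for k in range(5):
            r = [np.corrcoef(cents[k], planted[j])[0, 1] for j in range(5)]
            assert np.argmax(r) == k

    def test_cell_equal_to_centroid_maps_perfectly(self):
        cents = np.random.default_rng(0).normal(size=(4, 50))
        best, r = map_cell(cents[2], cents)
        assert best == 2
        assert r[2] == pytest.approx(1.0)

    def test_affine_invariance(self):
        cents = np.random.default_rng(1).normal(size=(4, 50))
        best, _ = map_cell(3.0 * cents[1] + 7.0, cents)
        assert best == 1

    def test_zero_variance_cell_unmappable(self):
        cents = np.random.default_rng(2).normal(size=(3, 20))
        best, r = map_cell(np.ones(20), cents)
        assert best == -1
        assert np.all(np.isnan(r))

    def test_moderate_noise_accuracy(self):
        spec = AtlasSpec(n_types=8, n_genes=1000, n_cells_per_type=50, seed=5)
        atlases, bundle, labels = generate_expression_bundle(
            spec, n_query_cells=80, query_noise=1.0)
        atlas = atlases[0]
        cents = build_centroids(atlas.log_expression(), atlas.cell_types,
                                atlas.type_names)
        order = {g: i for i, g in enumerate(atlas.genes)}
        q = normalize_expression(bundle)
        hits = 0
        for c in range(bundle.n_cells):
            best, _ = map_cell(q[:, c], cents)
            hits += atlas.type_names[best] == labels[c]
        assert hits / bundle.n_cells >= 0.95


# --------------------------------------------------------------------------
# QC, bootstrap, consensus
# --------------------------------------------------------------------------

GROUPS = {"t_mge": "MGE", "t_cge": "CGE", "t_exc": "excitatory"}
TYPES = list(GROUPS)


class TestRound1QC:
    def test_low_correlation_fails(self):
        res = round1_qc(np.array([0.35, 0.1, 0.1]), TYPES, GROUPS)
        assert not res.passed and res.reason == "low_correlation"

    def test_small_group_margin_fails(self):
        res = round1_qc(np.array([0.80, 0.79, 0.2]), TYPES, GROUPS)
        assert not res.passed and res.reason == "ambiguous_group"

    def test_clear_assignment_passes(self):
        res = round1_qc(np.array([0.80, 0.75, 0.2]), TYPES, GROUPS)
        assert res.passed and res.group == "MGE"

    def test_non_neural_fails(self):
        res = round1_qc(np.array([0.9, 0.2, 0.2]), TYPES, GROUPS,
                        neural_of_type={"t_mge": False})
        assert not res.passed and res.reason == "non_neural"


class TestBootstrap:
    def test_confidence_sums_to_one(self):
        rng = np.random.default_rng(0)
        cents = rng.normal(size=(5, 100))
        conf = bootstrap_confidence(cents[0] + rng.normal(scale=0.5, size=100),
                                    cents, n_boot=100, rng=0)
        assert conf.sum() == pytest.approx(1.0, abs=1e-9)

    def test_well_separated_type_gets_full_confidence(self):
        rng = np.random.default_rng(1)
        cents = rng.normal(size=(5, 200)) * 5.0
        conf = bootstrap_confidence(cents[3], cents, n_boot=100, rng=0)
        assert conf[3] >= 0.99

    def test_identical_centroids_split_confidence(self):
        rng = np.random.default_rng(2)
        c = rng.normal(size=100)
        cents = np.stack([c, c, rng.normal(size=100)])
        conf = bootstrap_confidence(c + rng.normal(scale=0.05, size=100),
                                    cents, n_boot=200, rng=0)
        # symmetric duplicates share essentially all the mass
        assert conf[0] + conf[1] >= 0.95
        assert conf[2] <= 0.05

    def test_seeded_reproducibility(self):
        rng = np.random.default_rng(3)
        cents = rng.normal(size=(4, 80))
        cell = cents[1] + rng.normal(scale=0.8, size=80)
        c1 = bootstrap_confidence(cell, cents, n_boot=50, rng=42)
        c2 = bootstrap_confidence(cell, cents, n_boot=50, rng=42)
        assert np.array_equal(c1, c2)


class TestConsensus:
    def test_single_atlas_passthrough(self):
        t, c = consensus_assignment([np.array([0.7, 0.3])], ["a", "b"])
        assert t == "a" and np.allclose(c, [0.7, 0.3])

    def test_average_of_two_atlases(self):
        t, c = consensus_assignment(
            [np.array([0.6, 0.4]), np.array([0.2, 0.8])], ["a", "b"])
        assert t == "b"
        assert np.allclose(c, [0.4, 0.6])


class TestEndToEnd:
    def test_noiseless_query_maps_to_true_type(self):
        spec = AtlasSpec(n_types=6, n_genes=600, n_cells_per_type=40, seed=7)
        atlases, bundle, labels = generate_expression_bundle(
            spec, n_query_cells=12, query_noise=0.0)
        res = assign_ttypes(bundle, atlases[0], atlases, n_boot=20, seed=0,
                            round1_genes=300, round2_genes=150)
        t = res.table
        assert t["qc_pass"].all()
        assert (t["final_type"].to_numpy() == labels).all()
        for cid, conf in res.consensus.items():
            assert conf.sum() == pytest.approx(1.0, abs=1e-9)

    def test_assignment_reproducible_given_seed(self):
        spec = AtlasSpec(n_types=4, n_genes=400, n_cells_per_type=30, seed=9)
        atlases, bundle, _ = generate_expression_bundle(spec, n_query_cells=8)
        r1 = assign_ttypes(bundle, atlases[0], atlases, n_boot=20, seed=5,
                           round1_genes=200, round2_genes=100)
        r2 = assign_ttypes(bundle, atlases[0], atlases, n_boot=20, seed=5,
                           round1_genes=200, round2_genes=100)
        assert r1.table.equals(r2.table)
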