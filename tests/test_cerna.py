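"""Triplet-rule network inference against brute-force enumeration."""

import numpy as np
import pytest
from scipy import stats

from cernapipe.cerna import (InferenceConfig, build_primary_network,
                             correlation_matrices, infer_corr_only_edges,
                             infer_db_edges, pearson_with_p)
from cernapipe.datatypes import InteractionDB, RNAClass
from cernapipe.network import CORRELATION_ONLY, DB_VALIDATED
from cernapipe.simulate import generate
from conftest import make_dataset, small_generator_config
from oracles import brute_force_primary_edges


class TestPearson:
    @pytest.mark.parametrize("x, y, r_expect, p_expect", [
        ([1, 2, 3], [2, 4, 6], 1.0, 0.0),
        ([1, 2, 3], [3, 2, 1], -1.0, 0.0),
        ([1, 2, 3, 4], [1, 3, 2, 4], 0.8, None),
    ])
    def test_known_values(self, x, y, r_expect, p_expect):
        r, p = pearson_with_p(np.array(x, float), np.array(y, float))
        assert r == pytest.approx(r_expect, abs=1e-12)
        if p_expect is not None:
            assert p == pytest.approx(p_expect, abs=1e-12)
        else:
            # cross-check p against the t-distribution formula directly
            t = r_expect * np.sqrt((len(x) - 2) / (1 - r_expect ** 2))
            assert p == pytest.approx(2 * stats.t.sf(t, len(x) - 2), rel=1e-10)

    def test_matches_scipy(self, rng):
        for _ in range(25):
            x, y = rng.normal(size=(2, 12))
            r, p = pearson_with_p(x, y)
            ref = stats.pearsonr(x, y)
            assert r == pytest.approx(ref.statistic, abs=1e-10)
            assert p == pytest.approx(ref.pvalue, rel=1e-6)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            pearson_with_p(np.ones(5), np.arange(5.0))

    def test_matrix_agrees_with_scalar(self, rng):
        x = rng.normal(size=(6, 15))
        r, p = correlation_matrices(x)
        for i in range(6):
            for j in range(i + 1, 6):
                ri, pi = pearson_with_p(x[i], x[j])
                assert r[i, j] == pytest.approx(ri, abs=1e-12)
                assert p[i, j] == pytest.approx(pi, rel=1e-10)


def _triplet_dataset(rho=0.95, n=60, flip_db=True, seed=0):
    """One miRNA anti-correlated with an mRNA and an lncRNA (positively
    coupled), plus an uncorrelated bystander."""
    rng = np.random.default_rng(seed)
    m = rng.normal(size=n)
    noise = np.sqrt(1 / rho - 1)
    mk = lambda s: np.exp(0.4 * (s * m + noise * rng.normal(size=n)))
    values = np.vstack([mk(-1), mk(+1), mk(+1), np.exp(rng.normal(size=n))])
    classes = {"mir_1": RNAClass.MIRNA, "mRNA_1": RNAClass.MRNA,
               "lnc_1": RNAClass.LNCRNA, "mRNA_2": RNAClass.MRNA}
    db = InteractionDB(pairs={("mir_1", "mRNA_1"), ("mir_1", "lnc_1")}) if flip_db \
        else InteractionDB(pairs=set())
    return make_dataset(values, classes), db


class TestDbRoute:
    def test_triplet_with_db_evidence_yields_edge(self):
        ds, db = _triplet_dataset()
        edges = infer_db_edges(ds, db)
        assert len(edges) == 1
        a, b, w, mirnas, evidence = edges[0]
        assert {a, b} == {"mRNA_1", "lnc_1"}
        assert mirnas == ("mir_1",) and evidence == DB_VALIDATED and w > 0.4

    def test_without_db_pairs_no_edge(self):
        ds, _ = _triplet_dataset(flip_db=False)
        assert infer_db_edges(ds, InteractionDB(pairs=set())) == []

    def test_threshold_is_strict(self):
        # correlation below (0.39) or at (0.40) the threshold never passes
        cfg_40 = InferenceConfig(corr_threshold=0.4)
        ds, db = _triplet_dataset(rho=0.95)
        r = np.corrcoef(ds.values.loc["mRNA_1"], ds.values.loc["lnc_1"])[0, 1]
        at_threshold = InferenceConfig(corr_threshold=r)  # exactly r: strict > fails
        assert infer_db_edges(ds, db, cfg_40) != []
        assert infer_db_edges(ds, db, at_threshold) == []


class TestCorrOnlyRoute:
    def test_circ_mrna_triplet_without_db(self):
        ds, _ = _triplet_dataset()
        # relabel the lncRNA as circRNA: correlation-only route applies
        classes = ds.classes.replace(RNAClass.LNCRNA, RNAClass.CIRCRNA)
        ds = make_dataset(ds.values.to_numpy(), classes.to_dict())
        edges = infer_corr_only_edges(ds)
        pairs = {(a, b) for a, b, *_ in edges}
        assert ("lnc_1", "mRNA_1") in pairs  # id kept, class now circRNA
        assert all(e[-1] == CORRELATION_ONLY for e in edges)

    def test_no_mirna_no_edges(self, rng):
        values = np.exp(rng.normal(size=(2, 30)))
        classes = {"circ_1": RNAClass.CIRCRNA, "mRNA_1": RNAClass.MRNA}
        assert infer_corr_only_edges(make_dataset(values, classes)) == []

    def test_positive_pair_without_mirna_arm_is_rejected(self, rng):
        # two positively coupled circRNAs, one unrelated miRNA
        m = rng.normal(size=80)
        values = np.vstack([np.exp(m + 0.1 * rng.normal(size=80)),
                            np.exp(m + 0.1 * rng.normal(size=80)),
                            np.exp(rng.normal(size=80))])
        classes = {"circ_1": RNAClass.CIRCRNA, "circ_2": RNAClass.CIRCRNA,
                   "mir_1": RNAClass.MIRNA}
        assert infer_corr_only_edges(make_dataset(values, classes)) == []


class TestPrimaryNetwork:
    def test_no_passing_triplets_empty_network(self, rng):
        values = np.exp(rng.normal(size=(6, 40)))
        classes = {"mRNA_1": RNAClass.MRNA, "mRNA_2": RNAClass.MRNA,
                   "lnc_1": RNAClass.LNCRNA, "circ_1": RNAClass.CIRCRNA,
                   "mir_1": RNAClass.MIRNA, "mir_2": RNAClass.MIRNA}
        net = build_primary_network(make_dataset(values, classes),
                                    InteractionDB(pairs={("mir_1", "mRNA_1")}))
        assert net.n_nodes == 0 and net.n_edges == 0

    def test_oracle_equivalence_random_instances(self):
        """Inference equals literal enumeration of every (pair, miRNA) rule."""
        for seed in range(6):
            cohort = generate(small_generator_config(
                seed=seed, subtypes=(("A", 50),),
                n_genes={RNAClass.MRNA: 12, RNAClass.LNCRNA: 6,
                         RNAClass.CIRCRNA: 6, RNAClass.MIRNA: 6},
                n_common_triplets=0, n_specific_triplets=3,
                n_planted_biomarkers=0, n_outliers=0, n_decoy_interactions=10))
            ds, db = cohort.expression["A"], cohort.interactions
            net = build_primary_network(ds, db)
            expected = brute_force_primary_edges(ds, db)
            assert net.edge_set() == set(expected)
            for (a, b), mirnas in expected.items():
                assert set(net.graph.edges[a, b]["supporting_mirnas"]) == mirnas

    def test_sample_permutation_invariance(self):
        cohort = generate(small_generator_config(seed=3, subtypes=(("A", 40),),
                                                 n_outliers=0))
        ds, db = cohort.expression["A"], cohort.interactions
        perm = np.random.default_rng(1).permutation(ds.samples).tolist()
        net1 = build_primary_network(ds, db)
        net2 = build_primary_network(ds.subset_samples(perm), db)
        assert net1.edge_set() == net2.edge_set()
        assert net1.node_set() == net2.node_set()

    def test_monotone_in_thresholds(self):
        cohort = generate(small_generator_config(seed=4, subtypes=(("A", 60),),
                                                 n_outliers=0))
        ds, db = cohort.expression["A"], cohort.interactions
        loose = build_primary_network(ds, db, InferenceConfig(0.3, 0.05))
        tight = build_primary_network(ds, db, InferenceConfig(0.5, 0.01))
        assert tight.edge_set() <= loose.edge_set()

    def test_planted_recovery_across_subtypes(self):
        """Each subtype's primary network contains its planted edges."""
        found = total = 0
        for seed in range(5):
            cohort = generate(small_generator_config(seed=seed, n_outliers=0,
                subtypes=tuple(zip("ABCDE", (100,) * 5))))
            for label, ds in cohort.expression.items():
                net = build_primary_network(ds, cohort.interactions)
                expected = cohort.truth.expected_edges(label)
                found += len(expected & net.edge_set())
                total += len(expected)
        assert found / total >= 0.9

    def test_constant_gene_excluded_not_fatal(self, caplog):
        ds, db = _triplet_dataset()
        values = ds.values.copy()
        values.loc["mRNA_2"] = 1.0
        ds2 = make_dataset(values.to_numpy(), ds.classes.to_dict())
        with caplog.at_level("WARNING"):
            net = build_primary_network(ds2, db)
        assert "constant" in caplog.text
        assert net.edge_set() == {("lnc_1", "mRNA_1")}
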