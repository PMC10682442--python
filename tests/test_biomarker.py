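"""TMM, the conditional NB exact test, biomarker intersection, SVM CV."""

import math

import numpy as np
import pandas as pd
import pytest

from cernapipe.biomarker import (intersect_biomarkers,
                                 nb_exact_test, normalize_counts, pairwise_deg,
                                 svm_cv_evaluate, tmm_factors, BiomarkerSet)
from cernapipe.simulate import generate
from conftest import small_generator_config


def _counts(mat, prefix="s"):
    mat = np.asarray(mat)
    return pd.DataFrame(mat, index=[f"g{i}" for i in range(mat.shape[0])],
                        columns=[f"{prefix}{j}" for j in range(mat.shape[1])])


class TestTMM:
    def test_identical_samples_unit_factors(self):
        c = _counts(np.tile([[10], [50], [200]], (1, 4)))
        np.testing.assert_allclose(tmm_factors(c), 1.0, atol=1e-12)

    def test_pure_depth_difference_unit_factors(self):
        # doubling all counts changes library size, not composition
        base = np.array([[10], [50], [200], [7], [90]])
        c = _counts(np.hstack([base, 2 * base]))
        np.testing.assert_allclose(tmm_factors(c), 1.0, atol=1e-9)

    def test_gene_permutation_invariance(self, rng):
        mat = rng.integers(1, 500, size=(50, 6))
        c = _counts(mat)
        perm = rng.permutation(50)
        shuffled = c.iloc[perm]
        np.testing.assert_allclose(tmm_factors(c), tmm_factors(shuffled), atol=1e-12)

    def test_geometric_mean_one(self, rng):
        mat = rng.integers(0, 300, size=(80, 5))
        mat[:, 0] *= 3
        f = tmm_factors(_counts(mat))
        assert np.exp(np.mean(np.log(f))) == pytest.approx(1.0, abs=1e-12)

    def test_all_zero_sample_rejected(self):
        c = _counts([[0, 5], [0, 2]])
        with pytest.raises(ValueError, match="all-zero"):
            tmm_factors(c)

    def test_normalize_counts_joint(self):
        a, b = _counts([[10], [20]], "a"), _counts([[10], [20]], "b")
        f = normalize_counts(a, b)
        assert list(f.index) == ["a0", "b0"]


class TestNBExact:
    def test_identical_groups_null(self):
        a = _counts([[10, 12], [50, 48]], "a")
        res = nb_exact_test(a, a.rename(columns={"a0": "b0", "a1": "b1"}))
        np.testing.assert_allclose(res["log2fc"], 0.0, atol=1e-12)
        np.testing.assert_allclose(res["p"], 1.0)

    @pytest.mark.parametrize("ya, yb", [(10, 0), (7, 3)])
    def test_dispersion_zero_matches_binomial_enumeration(self, ya, yb):
        """With phi = 0 and equal effective libraries, the conditional test is
        the two-sided exact binomial at p = 1/2 (doubled smaller tail)."""
        # identical background block keeps the TMM-effective library sizes
        # exactly equal, so the tested gene's totals enter unscaled
        bg = np.full((20, 2), 100)
        a = _counts(np.vstack([np.array([[ya, ya]]), bg]), "a")
        b = _counts(np.vstack([np.array([[yb, yb]]), bg]), "b")
        res = nb_exact_test(a, b, dispersion=0.0)
        t = 2 * (ya + yb)
        pmf = [math.comb(t, k) * 0.5 ** t for k in range(t + 1)]
        expect = min(1.0, 2 * min(sum(pmf[: 2 * ya + 1]), sum(pmf[2 * ya:])))
        assert res.loc["g0", "p"] == pytest.approx(expect, abs=1e-12)

    def test_group_swap_symmetry(self, rng):
        a = _counts(rng.integers(0, 200, size=(30, 8)), "a")
        b = _counts(rng.integers(0, 200, size=(30, 6)), "b")
        ab = nb_exact_test(a, b, dispersion=0.2)
        ba = nb_exact_test(b, a, dispersion=0.2)
        np.testing.assert_allclose(ab["p"], ba["p"], atol=1e-10)
        np.testing.assert_allclose(ab["log2fc"], -ba["log2fc"], atol=1e-10)

    def test_all_zero_gene(self):
        a = _counts([[0, 0], [10, 12]], "a")
        b = _counts([[0, 0], [9, 14]], "b")
        res = nb_exact_test(a, b)
        assert res.loc["g0", "p"] == 1.0 and res.loc["g0", "log2fc"] == 0.0

    def test_null_type_one_error(self, rng):
        phi, mu, n = 0.2, 100.0, 20
        lam = rng.gamma(1 / phi, phi * mu, size=(2000, 2 * n))
        counts = rng.poisson(lam)
        res = nb_exact_test(_counts(counts[:, :n], "a"), _counts(counts[:, n:], "b"),
                            dispersion=phi)
        assert 0.035 <= (res["p"] < 0.05).mean() <= 0.065


@pytest.fixture(scope="module")
def cohort():
    return generate(small_generator_config(seed=21))


class TestPairwiseAndIntersection:

    def test_planted_biomarker_passes_all_comparisons(self, cohort):
        genes = cohort.truth.planted_biomarkers["A"] + ["mRNA_0050", "circ_0020"]
        deg = pairwise_deg(cohort.counts, "A", genes)
        assert len(deg) == 4
        for res in deg.values():
            for g in cohort.truth.planted_biomarkers["A"]:
                assert bool(res.table.loc[g, "passed"])
        bio = intersect_biomarkers(deg)
        assert set(cohort.truth.planted_biomarkers["A"]) <= set(bio.genes)

    def test_strict_logfc_threshold(self):
        table = pd.DataFrame({"log2fc": [0.5, 0.51], "p": [1e-6, 1e-6],
                              "fdr": [1e-6, 1e-6]}, index=["gA", "gB"])
        passed = (table["fdr"] < 0.05) & (table["log2fc"].abs() > 0.5)
        assert not passed["gA"] and passed["gB"]  # documents the rule used

    def test_empty_gene_list(self, cohort):
        deg = pairwise_deg(cohort.counts, "A", [])
        assert all(len(r.table) == 0 for r in deg.values())
        assert intersect_biomarkers(deg).genes == []

    def test_partial_passer_excluded(self, cohort):
        genes = cohort.truth.planted_biomarkers["A"]
        deg = pairwise_deg(cohort.counts, "A", genes)
        # force a failure in one comparison
        key = next(iter(deg))
        deg[key].table.loc[genes[0], "passed"] = False
        assert genes[0] not in intersect_biomarkers(deg).genes

    def test_null_world_empty_intersection(self):
        empties = 0
        for seed in range(5):
            cohort = generate(small_generator_config(
                seed=seed, n_planted_biomarkers=0))
            genes = [f"mRNA_{i:04d}" for i in range(40, 55)]
            bio = intersect_biomarkers(pairwise_deg(cohort.counts, "A", genes))
            empties += not bio.genes
        assert empties >= 4


class TestSVM:
    def test_separable_biomarkers_auc_one(self):
        cohort = generate(small_generator_config(
            seed=5, biomarker_log2fc=4.0, noise_log_sd=0.2, n_outliers=0))
        bio = BiomarkerSet(subtype="A", table=pd.DataFrame(
            {"gene": cohort.truth.planted_biomarkers["A"]}))
        report = svm_cv_evaluate(dict(cohort.expression), bio, seed=0)
        assert report.fold_aucs == [1.0] * 5

    def test_determinism(self, rng):
        cohort = generate(small_generator_config(seed=6, n_outliers=0))
        bio = BiomarkerSet(subtype="B", table=pd.DataFrame(
            {"gene": cohort.truth.planted_biomarkers["B"]}))
        r1 = svm_cv_evaluate(dict(cohort.expression), bio, seed=7)
        r2 = svm_cv_evaluate(dict(cohort.expression), bio, seed=7)
        assert r1.fold_aucs == r2.fold_aucs
        pd.testing.assert_frame_equal(r1.roc_points, r2.roc_points)

    def test_empty_biomarkers_rejected(self, small_cohort):
        with pytest.raises(ValueError, match="empty biomarker"):
            svm_cv_evaluate(dict(small_cohort.expression),
                            BiomarkerSet(subtype="A"), seed=0)
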