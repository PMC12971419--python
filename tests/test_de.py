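"""Differential-expression layer: TMM, dispersion, exact test, GLM, BH, PCA.

The exact test and TMM are checked against independent brute-force oracles
(explicit enumeration with scipy distributions / explicit trim-set
construction), not against their own implementation.
"""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from deprofiler.io import AnalysisConfig, Contrast, CountMatrix, InputError, SampleMeta
from deprofiler.simulate import SyntheticScenario, generate_counts
from deprofiler import de as de_mod
from deprofiler.de import (
    DispersionEstimate,
    bh_fdr,
    call_degs,
    estimate_dispersion,
    exact_test,
    fit_two_factor_glm,
    log_norm_expression,
    pca_embedding,
    tmm_factors,
)


def _cm(array, genes=None, samples=None):
    array = np.asarray(array)
    genes = genes or [f"g{i}" for i in range(array.shape[0])]
    samples = samples or [f"s{j}" for j in range(array.shape[1])]
    return CountMatrix(pd.DataFrame(array, index=genes, columns=samples))


# ---------------------------------------------------------------------------
# TMM


class TestTMM:
    def test_identical_samples_give_unit_factors(self):
        cm = _cm([[10, 10], [50, 50], [3, 3]])
        f = tmm_factors(cm).factors
        np.testing.assert_allclose(f, [1.0, 1.0], atol=1e-12)

    def test_pure_depth_change_absorbed_by_library_size(self):
        base = np.array([[10], [50], [3], [200], [7], [40]])
        cm = _cm(np.hstack([base, 2 * base]))
        f = tmm_factors(cm).factors
        np.testing.assert_allclose(f, [1.0, 1.0], atol=1e-12)

    def test_composition_outlier_matches_trim_oracle(self):
        """One gene hogging sample B's reads: factor equals an independently
        coded weighted trimmed mean over the explicitly enumerated trim set."""
        obs = np.array([100, 80, 120, 90, 60, 5000], float)
        ref = np.array([110, 75, 130, 85, 65, 100], float)
        cm = _cm(np.column_stack([ref, obs]))
        got = tmm_factors(cm, ref_sample="s0").factors

        No, Nr = obs.sum(), ref.sum()
        m = np.log2((obs / No) / (ref / Nr))
        a = 0.5 * np.log2((obs / No) * (ref / Nr))
        w = 1.0 / ((No - obs) / (No * obs) + (Nr - ref) / (Nr * ref))
        n = len(m)
        lo_m, hi_m = int(np.floor(0.3 * n)) + 1, n - int(np.floor(0.3 * n))
        lo_a, hi_a = int(np.floor(0.05 * n)) + 1, n - int(np.floor(0.05 * n))
        keep = [
            i
            for i in range(n)
            if lo_m <= sorted(m).index(m[i]) + 1 <= hi_m
            and lo_a <= sorted(a).index(a[i]) + 1 <= hi_a
        ]
        expected = 2.0 ** (np.sum(w[keep] * m[keep]) / np.sum(w[keep]))
        # factors are rescaled to geometric mean one afterwards
        expected_pair = np.array([1.0, expected])
        expected_pair /= np.exp(np.mean(np.log(expected_pair)))
        np.testing.assert_allclose(got.to_numpy(), expected_pair, rtol=0.01)

    def test_all_zero_sample_rejected(self):
        with pytest.raises(InputError, match="all-zero"):
            tmm_factors(_cm([[1, 0], [2, 0]]))


class TestLogNorm:
    def test_single_cell_arithmetic(self):
        cm = _cm([[99]], samples=["s0"])
        norm = de_mod.NormFactors(
            factors=pd.Series([1.0], index=["s0"]),
            library_sizes=pd.Series([1e6], index=["s0"]),
        )
        val = log_norm_expression(cm, norm, prior_count=0.5).iloc[0, 0]
        assert val == pytest.approx(np.log2(99.5 / (1e6 + 1) * 1e6), abs=1e-9)

    def test_all_zero_counts_constant_matrix(self):
        cm = _cm(np.zeros((3, 2), dtype=int))
        norm = de_mod.NormFactors(
            factors=pd.Series([1.0, 1.0], index=["s0", "s1"]),
            library_sizes=pd.Series([1e5, 1e5], index=["s0", "s1"]),
        )
        out = log_norm_expression(cm, norm)
        assert out.nunique().nunique() == 1

    def test_joint_scaling_invariance(self):
        counts = np.array([[5, 9], [40, 31], [0, 2]])
        libs = pd.Series([1e5, 2e5], index=["s0", "s1"])
        norm1 = de_mod.NormFactors(
            factors=pd.Series([1.0, 1.0], index=["s0", "s1"]), library_sizes=libs
        )
        norm2 = de_mod.NormFactors(
            factors=pd.Series([1.0, 1.0], index=["s0", "s1"]),
            library_sizes=2 * libs,
        )
        a = log_norm_expression(_cm(counts), norm1)
        b = log_norm_expression(_cm(2 * counts), norm2)
        np.testing.assert_allclose(a.to_numpy(), b.to_numpy(), atol=1e-12)


# ---------------------------------------------------------------------------
# dispersion


def _nb_counts(phi, n_genes=2000, seed=0, mean_log2=(6.0, 1.0)):
    sc = SyntheticScenario(
        n_genes=n_genes,
        baseline_log2_mean=mean_log2,
        dispersion_phi0=phi,
        dispersion_a=0.0,
        library_size_log_sd=0.1,
        programs=[],
        seed=seed,
    )
    return generate_counts(sc)


class TestDispersion:
    def test_recovers_planted_common_dispersion(self):
        cm, metas, _ = _nb_counts(phi=0.1)
        norm = tmm_factors(cm)
        est = estimate_dispersion(cm, metas, norm)
        assert 0.08 < est.common < 0.12

    def test_poisson_data_near_zero(self):
        cm, metas, _ = _nb_counts(phi=0.0, n_genes=1000)
        norm = tmm_factors(cm)
        est = estimate_dispersion(cm, metas, norm)
        assert est.common < 0.02

    def test_infinite_prior_collapses_tagwise_to_common(self):
        cm, metas, _ = _nb_counts(phi=0.1, n_genes=300)
        norm = tmm_factors(cm)
        est = estimate_dispersion(cm, metas, norm, prior_df=1e9)
        np.testing.assert_allclose(est.tagwise, est.common, rtol=1e-12)

    def test_tagwise_nonnegative_and_finite(self):
        cm, metas, _ = _nb_counts(phi=0.2, n_genes=300)
        norm = tmm_factors(cm)
        est = estimate_dispersion(cm, metas, norm, prior_df=5)
        assert (est.tagwise >= 0).all() and np.isfinite(est.tagwise).all()


# ---------------------------------------------------------------------------
# exact test


def _exact_oracle(ya, yb, na, nb, phi):
    """Independent conditional enumeration with scipy's NB pmf."""
    t = ya + yb
    if t == 0:
        return 1.0
    mu = t / (na + nb)
    ra, rb = na / phi, nb / phi
    pa = stats.nbinom.pmf(np.arange(t + 1), ra, ra / (ra + na * mu))
    pb = stats.nbinom.pmf(t - np.arange(t + 1), rb, rb / (rb + nb * mu))
    joint = pa * pb
    obs = joint[ya]
    return float(joint[joint <= obs * (1 + 1e-9)].sum() / joint.sum())


class TestExactTest:
    def _setup(self, counts, phi=0.1):
        genes = [f"g{i}" for i in range(counts.shape[0])]
        samples = ["wt_tg_1", "wt_tg_2", "ko_tg_1", "ko_tg_2"]
        metas = [
            SampleMeta("wt_tg_1", "wt", "tg"),
            SampleMeta("wt_tg_2", "wt", "tg"),
            SampleMeta("ko_tg_1", "ko", "tg"),
            SampleMeta("ko_tg_2", "ko", "tg"),
        ]
        cm = _cm(counts, genes=genes, samples=samples)
        lib = cm.library_sizes.astype(float)
        norm = de_mod.NormFactors(
            factors=pd.Series(1.0, index=samples), library_sizes=lib
        )
        disp = DispersionEstimate(
            common=phi, tagwise=pd.Series(phi, index=genes), prior_df=10
        )
        contrast = Contrast("ko_vs_wt", ("ko", "tg"), ("wt", "tg"))
        return cm, metas, contrast, disp, norm

    def test_symmetric_counts_give_null_result(self):
        counts = np.array([[5, 7, 5, 7], [100, 90, 100, 90]])
        cm, metas, contrast, disp, norm = self._setup(counts)
        res = exact_test(cm, metas, contrast, disp, norm)
        np.testing.assert_allclose(res["log2fc"], 0.0, atol=1e-12)
        np.testing.assert_allclose(res["p"], 1.0, atol=1e-12)

    def test_swapping_groups_negates_log2fc(self):
        counts = np.array([[5, 7, 50, 60], [30, 20, 10, 5]])
        cm, metas, contrast, disp, norm = self._setup(counts)
        fwd = exact_test(cm, metas, contrast, disp, norm)
        rev = exact_test(
            cm,
            metas,
            Contrast("swap", ("wt", "tg"), ("ko", "tg")),
            disp,
            norm,
        )
        np.testing.assert_allclose(fwd["log2fc"], -rev["log2fc"], atol=1e-12)
        np.testing.assert_allclose(fwd["p"], rev["p"], atol=1e-12)

    @given(
        ya=st.integers(0, 100),
        yb=st.integers(0, 100),
        phi=st.sampled_from([0.01, 0.1, 0.5, 1.0]),
    )
    @settings(max_examples=300, deadline=None, derandomize=True)
    def test_matches_enumeration_oracle(self, ya, yb, phi):
        """Group-sum splits with totals <= 200 agree with the independent
        scipy-based enumeration to 1e-10."""
        got = de_mod._exact_pvalues(
            np.array([ya]), np.array([yb]), 2, 2, np.array([phi])
        )[0]
        want = _exact_oracle(ya, yb, 2, 2, phi)
        assert got == pytest.approx(want, abs=1e-10)

    def test_missing_group_is_error(self):
        counts = np.array([[1, 2, 3, 4]])
        cm, metas, _, disp, norm = self._setup(counts)
        bad = Contrast("none", ("ko", "nontg"), ("wt", "tg"))
        with pytest.raises(InputError, match="absent"):
            exact_test(cm, metas, bad, disp, norm)


# ---------------------------------------------------------------------------
# GLM


class TestGLM:
    def _full_design(self, counts, phi=0.05):
        genes = [f"g{i}" for i in range(counts.shape[0])]
        samples, metas = [], []
        for geno in ("wt", "ko"):
            for tg in ("nontg", "tg"):
                for r in (1, 2, 3):
                    sid = f"{geno}_{tg}_{r}"
                    samples.append(sid)
                    metas.append(SampleMeta(sid, geno, tg))
        cm = _cm(counts, genes=genes, samples=samples)
        norm = de_mod.NormFactors(
            factors=pd.Series(1.0, index=samples),
            library_sizes=pd.Series(1e4, index=samples),
        )
        disp = DispersionEstimate(
            common=phi, tagwise=pd.Series(phi, index=genes), prior_df=10
        )
        return cm, metas, disp, norm

    def test_flat_gene_has_null_coefficients(self):
        counts = np.full((1, 12), 50)
        cm, metas, disp, norm = self._full_design(counts)
        fit = fit_two_factor_glm(cm, metas, disp, norm)
        np.testing.assert_allclose(
            fit.coef.iloc[0, 1:], 0.0, atol=1e-6
        )  # non-intercept terms
        assert fit.lrt["interaction_p"].iloc[0] == pytest.approx(1.0, abs=1e-5)

    def test_interaction_coefficient_recovery(self, ad_like_run):
        """Planted log2 interaction of 2 recovered within +-0.3 (median
        over the strong interaction program) at n=5/group."""
        de = ad_like_run["de"]
        truth = ad_like_run["truth"]
        isg = truth.index[truth["program"] == "isg_interaction"]
        coefs = de.interaction.loc[de.interaction.index.intersection(isg), "coef_log2"]
        assert abs(coefs.median() - 2.0) < 0.3

    def test_requires_all_design_cells(self):
        counts = np.full((1, 12), 50)
        cm, metas, disp, norm = self._full_design(counts)
        broken = [m for m in metas if m.group != ("ko", "tg")]
        cm2 = CountMatrix(cm.counts[[m.sample_id for m in broken]])
        with pytest.raises(InputError, match="four design cells"):
            fit_two_factor_glm(cm2, broken, disp, norm)


# ---------------------------------------------------------------------------
# BH FDR


def _bh_reference(p):
    """Quadratic-time literal transcription of the step-up definition."""
    p = np.asarray(p, float)
    m = p.size
    q = np.empty(m)
    for i in range(m):
        candidates = [
            p[j] * m / (np.sum(p <= p[j]))
            for j in range(m)
            if p[j] >= p[i]
        ]
        q[i] = min(1.0, min(candidates))
    return q


class TestBH:
    def test_worked_example(self):
        np.testing.assert_allclose(
            bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04], atol=1e-12
        )

    def test_equal_and_singleton_inputs_unchanged(self):
        np.testing.assert_allclose(bh_fdr([0.2, 0.2, 0.2]), [0.2, 0.2, 0.2])
        np.testing.assert_allclose(bh_fdr([0.37]), [0.37])

    def test_na_passthrough(self):
        q = bh_fdr([0.01, np.nan, 0.04])
        assert np.isnan(q[1])
        np.testing.assert_allclose(q[[0, 2]], bh_fdr([0.01, 0.04]))

    @pytest.mark.parametrize("bad", [0.0, -0.1, 1.5])
    def test_out_of_range_rejected(self, bad):
        with pytest.raises(InputError):
            bh_fdr([0.5, bad])

    @given(
        st.lists(
            st.floats(min_value=1e-6, max_value=1.0, allow_nan=False),
            min_size=1,
            max_size=40,
        )
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_matches_quadratic_reference(self, pvals):
        np.testing.assert_allclose(
            bh_fdr(pvals), _bh_reference(pvals), atol=1e-12
        )

    def test_monotone_in_p_within_contrast(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(1e-6, 1, 500)
        q = bh_fdr(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()


# ---------------------------------------------------------------------------
# DEG calling and PCA


class TestDegsAndPCA:
    def test_threshold_application(self):
        tab = pd.DataFrame(
            {
                "log2fc": [0.5, -0.05, 3.0, -0.2, 0.15],
                "p": [0.001, 0.001, 0.1, 0.01, 0.02],
                "fdr": [0.01, 0.01, 0.2, 0.04, 0.06],
            },
            index=[f"g{i}" for i in range(5)],
        )
        de = de_mod.DEResult(pairwise={"c": tab}, interaction=tab[["p", "fdr"]])
        out = call_degs(de, "c", AnalysisConfig())
        assert len(out["fdr_only"]) == 3
        # of the three genes passing FDR < 0.05, one has positive and two
        # have negative fold changes
        assert (out["n_up"], out["n_down"]) == (1, 2)
        assert len(out["enrichment"]) == 2

    def test_empty_and_all_null_inputs(self):
        empty = pd.DataFrame(columns=["log2fc", "p", "fdr"])
        de = de_mod.DEResult(pairwise={"c": empty}, interaction=empty)
        out = call_degs(de, "c", AnalysisConfig())
        assert (out["n_up"], out["n_down"]) == (0, 0)

        tab = pd.DataFrame({"log2fc": [1.0, 2.0], "p": [1, 1], "fdr": [1.0, 1.0]})
        de = de_mod.DEResult(pairwise={"c": tab}, interaction=tab)
        out = call_degs(de, "c", AnalysisConfig())
        assert len(out["fdr_only"]) == 0

    def test_pca_duplicated_samples_coincide(self):
        rng = np.random.default_rng(1)
        base = rng.normal(size=(30, 3))
        mat = np.column_stack([base[:, 0], base[:, 0], base[:, 1], base[:, 2]])
        coords, var = pca_embedding(
            pd.DataFrame(mat, columns=["a", "a2", "b", "c"])
        )
        np.testing.assert_allclose(
            coords.loc["a"], coords.loc["a2"], atol=1e-9
        )
        assert (np.diff(var) <= 1e-12).all() and var.sum() <= 1 + 1e-9

    def test_pca_two_samples_single_component(self):
        coords, var = pca_embedding(
            pd.DataFrame(np.random.default_rng(0).normal(size=(10, 2)))
        )
        assert coords.shape[1] == 1

    def test_pca_constant_matrix_all_zero(self):
        coords, var = pca_embedding(pd.DataFrame(np.ones((5, 3))))
        np.testing.assert_allclose(coords, 0.0)
        np.testing.assert_allclose(var, 0.0)
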