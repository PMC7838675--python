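"""Conditional-likelihood inference: transmission table, likelihood oracle
equivalence, fitting, LRT and contrasts."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from triogxe.gxe_inference import (
    MODEL_SPECS,
    EstimableParams,
    InferenceError,
    conditional_child_distribution,
    conditional_loglik,
    fit_model,
    interaction_contrasts,
    linear_predictor,
    lrt,
    mendelian_probs,
    scan_snp,
)
from triogxe.stratification_surrogate import SurrogateAssignment

from conftest import make_dataset

# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------


def punnett_oracle(gm: int, gf: int) -> np.ndarray:
    """Transmission probabilities by explicit enumeration of the four
    parental allele transmissions (independent of the implementation)."""
    m_alleles = [1] * gm + [0] * (2 - gm)
    f_alleles = [1] * gf + [0] * (2 - gf)
    out = np.zeros(3)
    for a in m_alleles:
        for b in f_alleles:
            out[a + b] += 0.25
    return out


def brute_force_loglik(params, gm, gf, gc, e, x):
    """Per-trio construction of the full 3-point conditional distribution."""
    total = 0.0
    for i in range(len(gc)):
        t = punnett_oracle(gm[i], gf[i])
        w = np.array(
            [t[g] * np.exp(linear_predictor(g, e[i], x[i], params)) for g in range(3)]
        )
        total += np.log(w[gc[i]] / w.sum())
    return total


def random_params(rng, scale=1.0):
    b = rng.normal(scale=scale, size=4)
    return EstimableParams(*b, model_spec="adjusted")


# ---------------------------------------------------------------------------


class TestMendelianProbs:
    @pytest.mark.parametrize(
        "gm,gf,expected",
        [
            ((1), (1), (0.25, 0.5, 0.25)),
            ((2), (0), (0.0, 1.0, 0.0)),
            ((2), (1), (0.0, 0.5, 0.5)),
            ((0), (0), (1.0, 0.0, 0.0)),
        ],
    )
    def test_punnett_table(self, gm, gf, expected):
        assert mendelian_probs(gm, gf) == pytest.approx(expected)

    def test_all_pairs_match_enumeration_and_symmetry(self):
        for gm in range(3):
            for gf in range(3):
                p = mendelian_probs(gm, gf)
                assert p == pytest.approx(punnett_oracle(gm, gf))
                assert p == pytest.approx(mendelian_probs(gf, gm))
                assert p.sum() == pytest.approx(1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(InferenceError):
            mendelian_probs(3, 0)


class TestLinearPredictor:
    def test_zero_copies_always_zero(self):
        p = EstimableParams(1.0, 2.0, 3.0, 4.0)
        assert linear_predictor(0, 1, 1, p) == 0.0

    def test_all_betas_ln2_saturated(self):
        ln2 = np.log(2.0)
        p = EstimableParams(ln2, ln2, ln2, ln2)
        assert linear_predictor(2, 1, 1.0, p) == pytest.approx(8 * ln2)

    def test_fractional_surrogate(self):
        p = EstimableParams(beta_g=0.1, beta_gx=0.2)
        assert linear_predictor(1, 0, 0.5, p) == pytest.approx(0.2)


class TestConditionalLoglik:
    def test_all_params_zero_is_pure_mendelian(self, rng):
        gm = rng.integers(0, 3, size=50)
        gf = rng.integers(0, 3, size=50)
        gc = np.array(
            [rng.choice(3, p=punnett_oracle(a, b)) for a, b in zip(gm, gf)]
        )
        ds = make_dataset(gc[:, None], gm[:, None], gf[:, None])
        ll = conditional_loglik(EstimableParams(), ds)
        expected = sum(np.log(punnett_oracle(a, b)[c]) for a, b, c in zip(gm, gf, gc))
        assert ll == pytest.approx(expected, abs=1e-12)

    def test_hand_enumerated_single_trio(self):
        # gm=gf=1, child 2, e=1, bGE=ln2: P = 0.25*4 / (0.25 + 0.5*2 + 0.25*4)
        ds = make_dataset([[2]], [[1]], [[1]], exposure=[1.0])
        p = EstimableParams(beta_ge=np.log(2.0), model_spec="unadjusted")
        assert conditional_loglik(p, ds) == pytest.approx(np.log(4 / 9), abs=1e-12)

    def test_matches_brute_force_oracle(self, rng):
        n = 200
        gm = rng.integers(0, 3, size=n)
        gf = rng.integers(0, 3, size=n)
        gc = np.array(
            [rng.choice(3, p=punnett_oracle(a, b)) for a, b in zip(gm, gf)]
        )
        e = rng.integers(0, 2, size=n).astype(float)
        x = rng.random(n)
        ds = make_dataset(gc[:, None], gm[:, None], gf[:, None], exposure=e)
        for _ in range(10):
            params = random_params(rng)
            ll = conditional_loglik(params, ds, x)
            assert ll == pytest.approx(
                brute_force_loglik(params, gm, gf, gc, e, x), abs=1e-10
            )

    def test_inconsistent_trio_is_hard_error(self):
        ds = make_dataset([[2]], [[0]], [[0]], exposure=[0.0])
        with pytest.raises(InferenceError, match="Mendelian"):
            conditional_loglik(EstimableParams(), ds)

    @given(st.integers(0, 2), st.integers(0, 2), st.booleans(),
           st.floats(0, 1), st.integers(0, 2**32 - 1))
    @settings(max_examples=60, deadline=None)
    def test_normalization_and_kp_cancellation(self, gm, gf, e, x, seed):
        rng = np.random.default_rng(seed)
        params = random_params(rng)
        dist = conditional_child_distribution(gm, gf, float(e), x, params)
        assert dist.sum() == pytest.approx(1.0, abs=1e-12)
        t = punnett_oracle(gm, gf)
        assert (dist[t == 0] == 0).all()
        # adding a per-parental-class constant to all genotype weights is a
        # k_p shift: it must leave the conditional distribution unchanged
        eta = (params.beta_g + e * params.beta_ge + x * params.beta_gx
               + e * x * params.beta_gex)
        w = t * np.exp(np.arange(3) * eta) * np.exp(3.7)
        w = w / w.sum()
        assert dist == pytest.approx(w, abs=1e-12)


class TestFitModel:
    def test_grid_search_recovery_two_params(self, rng):
        # 50-trio fixture; MLE within one 0.01 grid step of dense search
        from triogxe.synthetic_cohort import (
            CAUSAL_SNP,
            simulate_cohort,
            single_population_scenario,
        )

        truth, structure = single_population_scenario(n_trios=50, seed=7)
        ds, _ = simulate_cohort(truth, structure)
        fit = fit_model(ds, None, "unadjusted", CAUSAL_SNP)
        j = ds.snp_index(CAUSAL_SNP)
        keep = ~np.isnan(ds.exposure)
        gm, gf = ds.geno_mother[keep, j], ds.geno_father[keep, j]
        gc, e = ds.geno_child[keep, j], ds.exposure[keep]
        grid = np.arange(-3.0, 3.0 + 1e-9, 0.01)
        bg, bge = np.meshgrid(grid, grid, indexing="ij")
        # collapse trios into unique (gm, gf, e, gc) cells, then broadcast
        cells = {}
        for a, b, ee, c in zip(gm, gf, e, gc):
            cells[(a, b, ee, c)] = cells.get((a, b, ee, c), 0) + 1
        ll = np.zeros_like(bg)
        for (a, b, ee, c), cnt in cells.items():
            t = punnett_oracle(a, b)
            eta = bg + ee * bge
            z = sum(t[g] * np.exp(g * eta) for g in range(3) if t[g] > 0)
            ll += cnt * (np.log(t[c]) + c * eta - np.log(z))
        i, j = np.unravel_index(np.argmax(ll), ll.shape)
        assert fit.params.beta_g == pytest.approx(grid[i], abs=0.011)
        assert fit.params.beta_ge == pytest.approx(grid[j], abs=0.011)
        assert fit.loglik >= ll[i, j] - 1e-9

    def test_reduced_model_equivalence(self, small_cohort):
        # adjusted spec with the adjustment terms pinned at 0 reproduces the
        # unadjusted loglik exactly
        ds, _ = small_cohort
        x = (np.asarray(ds.sra_label) == "European").astype(float)
        beta = EstimableParams(0.23, -0.41, 0.0, 0.0, model_spec="adjusted")
        ll_adj = conditional_loglik(beta, ds, x, "sim_test")
        beta_u = EstimableParams(0.23, -0.41, model_spec="unadjusted")
        ll_un = conditional_loglik(beta_u, ds, x, "sim_test")
        assert ll_adj == pytest.approx(ll_un, abs=1e-10)

    def test_degenerate_surrogate_falls_back_to_unadjusted(self, small_cohort):
        ds, _ = small_cohort
        x = np.zeros(len(ds))  # all trios in one stratum
        fit = fit_model(ds, x, "adjusted", "sim_test")
        assert fit.params.model_spec == "unadjusted"
        assert "dropped_gexhat" in fit.identifiability_flags

    def test_no_informative_trios_rejected(self):
        ds = make_dataset([[0], [2]], [[0], [2]], [[0], [2]], exposure=[0, 1])
        with pytest.raises(InferenceError, match="informative"):
            fit_model(ds, None, "unadjusted")

    def test_main_effect_invisibility(self, rng):
        # exposure/surrogate main effects shift ascertainment rates but not
        # the conditional likelihood surface: same transmissions -> same fit
        from dataclasses import replace as dreplace

        from triogxe.synthetic_cohort import (
            CAUSAL_SNP,
            simulate_cohort,
            single_population_scenario,
        )

        truth, structure = single_population_scenario(
            beta_g=0.3, beta_ge=0.0, n_trios=800, seed=17
        )
        base, _ = simulate_cohort(truth, structure)
        fit_a = fit_model(base, None, "unadjusted", CAUSAL_SNP)
        shifted, _ = simulate_cohort(
            dreplace(truth, beta_e=0.9), structure,
            rng=np.random.default_rng(555),
        )
        fit_b = fit_model(shifted, None, "unadjusted", CAUSAL_SNP)
        # estimates agree within joint 3-SE Monte Carlo error
        se = np.hypot(fit_a.se("beta_g"), fit_b.se("beta_g"))
        assert abs(fit_a.params.beta_g - fit_b.params.beta_g) < 3 * se


class TestLRT:
    @pytest.mark.parametrize(
        "stat,df,p", [(5.991, 2, 0.0500), (3.841, 1, 0.0500), (0.0, 2, 1.0)]
    )
    def test_chi_square_tail(self, stat, df, p):
        assert stats.chi2.sf(stat, df) == pytest.approx(p, abs=5e-5)

    def test_nested_fits_and_errors(self, small_cohort):
        ds, _ = small_cohort
        x = (np.asarray(ds.sra_label) == "European").astype(float)
        full = fit_model(ds, x, "adjusted", "sim_test")
        null = fit_model(ds, x, "adjusted_null", "sim_test")
        res = lrt(full, null)
        assert res.df == 2 and res.statistic >= 0
        assert res.p == pytest.approx(stats.chi2.sf(res.statistic, 2))
        with pytest.raises(InferenceError):
            lrt(null, full)  # not nested
        with pytest.raises(InferenceError):
            lrt(full, full)  # same free parameters -> df 0

    def test_mismatched_trio_sets_rejected(self, small_cohort):
        ds, _ = small_cohort
        x = (np.asarray(ds.sra_label) == "European").astype(float)
        full = fit_model(ds, x, "adjusted", "sim_test")
        null = fit_model(
            ds, x, "adjusted_null", "sim_test",
            trio_mask=np.arange(len(ds)) < 400,
        )
        with pytest.raises(InferenceError, match="different trios"):
            lrt(full, null)


class TestContrasts:
    def test_reference_closed_form(self, small_cohort):
        ds, _ = small_cohort
        x = (np.asarray(ds.sra_label) == "European").astype(float)
        fit = fit_model(ds, x, "adjusted", "sim_test")
        ref = interaction_contrasts(fit, "reference")
        i = fit.free_names.index("beta_ge")
        se = np.sqrt(fit.vcov[i, i])
        assert ref.estimate == pytest.approx(np.exp(fit.params.beta_ge))
        assert ref.ci_lo == pytest.approx(np.exp(fit.params.beta_ge - 1.96 * se))
        # bGE=0, SE=1 closed form: CI (0.1408, 7.099)
        assert np.exp(-1.96) == pytest.approx(0.1408, abs=1e-4)
        assert np.exp(1.96) == pytest.approx(7.099, abs=5e-3)

    def test_comparison_variance_combines_covariance(self, small_cohort):
        ds, _ = small_cohort
        x = (np.asarray(ds.sra_label) == "European").astype(float)
        fit = fit_model(ds, x, "adjusted", "sim_test")
        cmp_ = interaction_contrasts(fit, "comparison")
        i = fit.free_names.index("beta_ge")
        j = fit.free_names.index("beta_gex")
        est = fit.params.beta_ge + fit.params.beta_gex
        se = np.sqrt(fit.vcov[i, i] + fit.vcov[j, j] + 2 * fit.vcov[i, j])
        assert cmp_.estimate == pytest.approx(np.exp(est))
        assert cmp_.ci_hi == pytest.approx(np.exp(est + 1.96 * se))


class TestScanSnp:
    def test_monomorphic_snp_gives_na_row(self, small_cohort):
        ds, _ = small_cohort
        ds = ds.subset_snps(["sim_causal"])
        ds.geno_child[:] = 0
        ds.geno_mother[:] = 0
        ds.geno_father[:] = 0
        row = scan_snp(ds, 0)
        assert np.isnan(row["p_unadj_1df"])
        assert "informative" in row["flags"]

    def test_surrogate_swap_leaves_2df_lrt_unchanged(self, small_cohort):
        # swapping which group is coded 1 negates bGX/bGEX but cannot change
        # the likelihood-ratio statistic
        ds, _ = small_cohort
        lab = np.asarray(ds.sra_label)
        x = (lab == "European").astype(float)
        full = fit_model(ds, x, "adjusted", "sim_test")
        null = fit_model(ds, x, "adjusted_null", "sim_test")
        full_s = fit_model(ds, 1.0 - x, "adjusted", "sim_test")
        null_s = fit_model(ds, 1.0 - x, "adjusted_null", "sim_test")
        assert lrt(full, null).statistic == pytest.approx(
            lrt(full_s, null_s).statistic, abs=1e-6
        )
        assert full_s.params.beta_gex == pytest.approx(
            -full.params.beta_gex, abs=1e-6
        )
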