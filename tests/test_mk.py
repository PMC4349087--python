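"""MK tables, the multilocus Poisson likelihood, and model-selection arithmetic."""

import math

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.special import gammaln
from scipy.stats import chi2

from polydiv.errors import UndefinedStatisticError
from polydiv.mk import (
    MKCountTable,
    aicc,
    akaike_weights,
    alpha_point_estimate,
    build_mk_table,
    chi_square_upper_tail,
    compare_mk_models,
    fit_multilocus_mk,
    likelihood_ratio,
    sample_mk_counts,
)
from polydiv.simulate import CodingLocusConfig, simulate_coding_locus

from conftest import make_alignment


class TestBuildMKTable:
    def test_fixed_synonymous_differences_only(self):
        # ingroup monomorphic; outgroup differs at two synonymous positions
        ing = "ATGTTTGGGCCC"
        out = "ATGTTCGGACCC"  # TTT->TTC syn, GGG->GGA syn
        aln = make_alignment([ing, ing, ing], out, coding=[(0, 12, 0)])
        t = build_mk_table(aln)
        assert (t.Ps, t.Pn, t.Ds, t.Dn) == (0, 0, 2, 0)

    def test_segregating_nonsynonymous_site(self):
        a = "ATGAAA"
        b = "ATGGAA"  # AAA->GAA Lys->Glu
        aln = make_alignment([a] * 2 + [b] * 2, a, coding=[(0, 6, 0)])
        t = build_mk_table(aln)
        assert (t.Ps, t.Pn, t.Ds, t.Dn) == (0, 1, 0, 0)

    def test_polymorphic_and_divergent_counts_as_polymorphism_only(self):
        a = "ATGTTT"
        b = "ATGTTC"
        aln = make_alignment([a, b], "ATGTTA", coding=[(0, 6, 0)])
        t = build_mk_table(aln)
        assert t.Ps == 1 and t.Ds == 0

    @pytest.mark.parametrize("seed", [0, 11, 42])
    def test_simulator_truth_exact_match(self, seed):
        aln, truth = simulate_coding_locus(CodingLocusConfig(seed=seed))
        t = build_mk_table(aln)
        assert (t.Ps, t.Pn, t.Ds, t.Dn) == tuple(
            truth.counts[k] for k in ("Ps", "Pn", "Ds", "Dn")
        )


class TestAlphaPointEstimate:
    def test_neutral_counts_give_zero(self):
        t = MKCountTable("x", Ps=10, Pn=10, Ds=10, Dn=10, L_syn=100, L_nonsyn=300)
        assert alpha_point_estimate(t) == 0.0

    def test_positive_alpha(self):
        t = MKCountTable("x", Ps=20, Pn=5, Ds=10, Dn=10, L_syn=100, L_nonsyn=300)
        assert alpha_point_estimate(t) == pytest.approx(0.75)

    def test_negative_alpha_permitted(self):
        t = MKCountTable("x", Ps=10, Pn=20, Ds=10, Dn=10, L_syn=100, L_nonsyn=300)
        assert alpha_point_estimate(t) == pytest.approx(-1.0)

    def test_undefined_when_ps_zero(self):
        t = MKCountTable("x", Ps=0, Pn=5, Ds=1, Dn=1, L_syn=100, L_nonsyn=300)
        with pytest.raises(UndefinedStatisticError):
            alpha_point_estimate(t)


def closed_form_m0_single_locus(Ps, Pn, Ds, Dn, Ls, La):
    """Joint-MLE closed form for one locus under M0 (stationarity conditions)."""
    A, B, C = Ps + Pn, Ds + Dn, Pn + Dn
    u = C * Ls / (A + B - C)  # u = La * f
    theta = A / (Ls + u)
    lam = B / (Ls + u)
    f = u / La
    ll = 0.0
    for x, mu in ((Ps, theta * Ls), (Pn, theta * La * f), (Ds, lam * Ls), (Dn, lam * La * f)):
        ll += x * math.log(mu) - mu - gammaln(x + 1)
    return theta, lam, f, ll


class TestMultilocusFit:
    def test_m0_matches_closed_form_oracle(self):
        # two identical loci: per-locus MLEs match the single-locus closed form
        t = MKCountTable("a", Ps=20, Pn=8, Ds=15, Dn=6, L_syn=300, L_nonsyn=900)
        t2 = MKCountTable("b", Ps=20, Pn=8, Ds=15, Dn=6, L_syn=300, L_nonsyn=900)
        fit = fit_multilocus_mk([t, t2], "M0", seed=0)
        theta, lam, f, ll = closed_form_m0_single_locus(20, 8, 15, 6, 300, 900)
        assert fit.theta == pytest.approx(theta, rel=1e-4)
        assert fit.lam == pytest.approx(lam, rel=1e-4)
        assert fit.constraint["a"] == pytest.approx(f, rel=1e-4)
        assert fit.logL == pytest.approx(2 * ll, abs=1e-5)

    def test_balanced_counts_closed_form(self):
        # Ps=Pn=Ds=Dn makes theta-hat = Ps/L_syn exactly
        t = MKCountTable("a", Ps=10, Pn=10, Ds=10, Dn=10, L_syn=200, L_nonsyn=600)
        fit = fit_multilocus_mk([t, t], "M0", seed=0)
        assert fit.theta == pytest.approx(10 / 200, rel=1e-4)
        assert fit.lam == pytest.approx(10 / 200, rel=1e-4)

    def test_model_nesting_on_simulated_data(self):
        rng = np.random.default_rng(3)
        f = rng.beta(2, 12, size=20)
        groups = ["immune"] * 10 + ["control"] * 10
        tabs = sample_mk_counts(
            0.026, 0.034, f, {"immune": 0.2, "control": 0.0},
            np.full(20, 300.0), np.full(20, 900.0), groups, rng,
        )
        fits = {m: fit_multilocus_mk(tabs, m, seed=1) for m in ("M0", "M1", "M2")}
        assert fits["M0"].logL <= fits["M1"].logL + 1e-6
        assert fits["M1"].logL <= fits["M2"].logL + 1e-6

    def test_group_difference_sign_recovery(self):
        # alpha_immune = 0.5 vs alpha_control = 0: M2 recovers the sign
        rng = np.random.default_rng(7)
        groups = ["immune"] * 20 + ["control"] * 20
        hits = 0
        reps = 50
        for _ in range(reps):
            f = rng.beta(2, 12, size=40)
            tabs = sample_mk_counts(
                0.026, 0.034, f, {"immune": 0.5, "control": 0.0},
                np.full(40, 300.0), np.full(40, 900.0), groups, rng,
            )
            fit = fit_multilocus_mk(tabs, "M2", n_restarts=2, seed=1)
            hits += fit.alpha["immune"] > fit.alpha["control"]
        assert hits / reps >= 0.95

    def test_m2_requires_both_groups(self):
        t = MKCountTable("a", Ps=5, Pn=5, Ds=5, Dn=5, L_syn=100, L_nonsyn=300)
        with pytest.raises(ValueError):
            fit_multilocus_mk([t, t], "M2")


class TestModelSelectionArithmetic:
    def test_lrt_statistic_from_printed_loglikelihoods(self):
        stat, df, p = likelihood_ratio(-235.44, -228.01, df=1)
        assert stat == pytest.approx(14.86, abs=1e-9)
        stat, df, p = likelihood_ratio(-181.22, -178.55, df=1)
        assert stat == pytest.approx(5.34, abs=1e-9)

    def test_identical_loglik_gives_zero_and_p_one(self):
        stat, df, p = likelihood_ratio(-100.0, -100.0, df=1)
        assert stat == 0.0
        assert p == 1.0

    def test_chi_square_tail_values(self):
        assert chi_square_upper_tail(0.64, 1) == pytest.approx(0.4237, abs=5e-5)
        assert chi_square_upper_tail(0.0, 3) == 1.0
        assert chi_square_upper_tail(9.1, 1) == pytest.approx(0.0026, abs=5e-5)

    @pytest.mark.parametrize("df", range(1, 11))
    def test_chi_square_tail_against_numeric_integration(self, df):
        for x in (0.5, 2.0, 8.5, 20.0):
            integral, _ = quad(chi2.pdf, x, np.inf, args=(df,))
            assert chi_square_upper_tail(x, df) == pytest.approx(integral, abs=1e-6)

    def test_aicc_arithmetic(self):
        assert aicc(-10.0, 2, 10) == pytest.approx(24 + 12 / 7)
        assert aicc(-10.0, 0, 10) == pytest.approx(20.0)
        # large-n limit is plain AIC
        assert aicc(-10.0, 3, 10**9) == pytest.approx(26.0, abs=1e-6)
        with pytest.raises(ValueError):
            aicc(-10.0, 9, 10)

    def test_akaike_weights_from_printed_aicc(self):
        w = akaike_weights([522.1, 511.3, 513.0])
        assert w[1] == pytest.approx(0.695, abs=0.005)
        assert w[2] == pytest.approx(0.302, abs=0.005)
        assert w[0] == pytest.approx(0.003, abs=0.005)
        assert w.sum() == pytest.approx(1.0, abs=1e-12)

    def test_akaike_weight_edge_cases(self):
        assert akaike_weights([100.0])[0] == 1.0
        assert akaike_weights([5.0, 5.0]) == pytest.approx([0.5, 0.5])


def test_compare_mk_models_report_shape():
    rng = np.random.default_rng(5)
    f = rng.beta(2, 12, size=10)
    groups = ["immune"] * 5 + ["control"] * 5
    tabs = sample_mk_counts(
        0.026, 0.034, f, {"immune": 0.0, "control": 0.0},
        np.full(10, 300.0), np.full(10, 900.0), groups, rng,
    )
    fits, report = compare_mk_models(tabs, seed=2)
    assert list(report["model"]) == ["M0", "M1", "M2"]
    assert report["akaike_weight"].sum() == pytest.approx(1.0)
    assert report["logL"].is_monotonic_increasing
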