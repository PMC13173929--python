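import numpy as np
import pytest

from termwalk import (
    ModelFit,
    WalkSpec,
    akaike_weights,
    cohort_summary,
    fit_model,
    nll_biexp,
    nll_te,
    nll_tpl,
    sample_steps,
    select_model,
)


class TestNegativeLogLikelihoods:
    def test_tpl_single_point_closed_form(self):
        # at l = l_min with mu=2 on [1, 10]: p = C_TPL = 1/(1 - 0.1),
        # so nll = -ln(10/9)
        nll = nll_tpl(2.0, np.array([1.0]), 1.0, 10.0)
        assert nll == pytest.approx(-np.log(10 / 9), abs=1e-12)

    def test_te_uniform_limit(self):
        # lam -> 0: the truncated exponential tends to the uniform density
        lengths = np.array([1.0, 3.0, 5.5])
        nll = nll_te(1e-9, lengths, 0.5, 6.5)
        assert nll == pytest.approx(3 * np.log(6.0), rel=1e-6)

    def test_biexp_degenerates_to_te(self):
        lengths = np.linspace(1, 9, 40)
        a = nll_biexp(1.0, 0.7, 3.3, lengths, 0.5, 10.0)
        b = nll_te(0.7, lengths, 0.5, 10.0)
        assert a == pytest.approx(b, rel=1e-12)

    def test_domain_violation_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            nll_tpl(2.0, np.array([0.2, 3.0]), 1.0, 10.0)
        with pytest.raises(ValueError):
            nll_tpl(0.9, np.array([2.0]), 1.0, 10.0)


class TestAkaikeWeights:
    def test_equal_aics_symmetric(self):
        np.testing.assert_allclose(akaike_weights([100.0, 100.0, 100.0]), 1 / 3)

    def test_two_point_closed_form(self):
        w = akaike_weights([100.0, 102.0])
        expected = np.array([1.0, np.exp(-1.0)])
        np.testing.assert_allclose(w, expected / expected.sum())

    def test_weights_sum_to_one(self, rng):
        w = akaike_weights(rng.uniform(50, 500, size=6))
        assert w.sum() == pytest.approx(1.0, abs=1e-12)

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            akaike_weights([100.0, np.inf])


def fits_from_nll(nlls):
    models = ("TPL", "TE", "BiExp")
    params = ({"mu": 1.3}, {"lam": 1.0}, {"w": 0.5, "lam1": 5.0, "lam2": 0.3})
    return [
        ModelFit(model=m, params=p, nll=v, n=100)
        for m, p, v in zip(models, params, nlls)
    ]


class TestSelectModel:
    def test_decisive_winner(self):
        sel = select_model(fits_from_nll([100.0, 110.0, 108.0]))
        assert sel.winner == "TPL" and sel.decisive
        assert sel.weights.sum() == pytest.approx(1.0, abs=1e-12)

    def test_indecisive_lowest_aic(self):
        sel = select_model(fits_from_nll([100.0, 100.5, 99.0]))
        # BiExp has lowest nll but pays 2 extra parameters: AICs 202, 203, 204
        assert sel.winner == "TPL" and not sel.decisive

    def test_exact_tie_breaks_to_parsimony(self):
        # TE nll arranged so TE and BiExp AICs tie exactly at the minimum
        sel = select_model(fits_from_nll([105.0, 100.0, 98.0]))
        assert {f.model: f.aic for f in sel.fits}["TE"] == pytest.approx(
            {f.model: f.aic for f in sel.fits}["BiExp"]
        )
        assert sel.winner == "TE"

    def test_aic_identity(self):
        fit = fits_from_nll([100.0, 100.0, 100.0])[2]
        assert fit.aic == 2 * 3 + 2 * fit.nll


class TestFitModel:
    def test_tpl_matches_grid_search_oracle(self):
        spec = WalkSpec(model="TPL", mu=1.5, l_min=0.5, l_max=200.0)
        lengths = sample_steps(spec, 500, seed=11)
        fit = fit_model("TPL", lengths, l_min=0.5, l_max=200.0)
        grid = np.linspace(1.001, 5.0, 10_000)
        nlls = [nll_tpl(m, lengths, 0.5, 200.0) for m in grid]
        assert fit.params["mu"] == pytest.approx(grid[np.argmin(nlls)], abs=1e-3)

    def test_te_untruncated_limit_closed_form(self):
        spec = WalkSpec(model="TE", lam=0.8, l_min=0.5, l_max=np.inf)
        lengths = sample_steps(spec, 10_000, seed=12)
        fit = fit_model("TE", lengths, l_min=0.5)
        # with l_max far in the tail the MLE approaches 1/(mean - l_min)
        assert fit.params["lam"] == pytest.approx(
            1.0 / (lengths.mean() - 0.5), rel=0.02
        )

    def test_biexp_recovery(self):
        # l_min well below 1/lam1 keeps the fast component identifiable
        spec = WalkSpec(
            model="BiExp", w=0.7, lam1=5.0, lam2=0.5, l_min=0.1, l_max=np.inf
        )
        lengths = sample_steps(spec, 10_000, seed=13)
        fit = fit_model("BiExp", lengths, l_min=0.1)
        assert fit.params["w"] == pytest.approx(0.7, abs=0.05)
        assert fit.params["lam1"] == pytest.approx(5.0, abs=0.5)
        assert fit.params["lam2"] == pytest.approx(0.5, abs=0.05)
        assert fit.params["lam1"] > fit.params["lam2"]

    def test_mu_invariant_to_rescaling(self):
        spec = WalkSpec(model="TPL", mu=1.4, l_min=0.5, l_max=100.0)
        lengths = sample_steps(spec, 2000, seed=14)
        a = fit_model("TPL", lengths, l_min=0.5, l_max=100.0).params["mu"]
        b = fit_model("TPL", 7 * lengths, l_min=3.5, l_max=700.0).params["mu"]
        assert a == pytest.approx(b, abs=1e-6)

    def test_minimum_sample_size(self):
        with pytest.raises(ValueError, match="at least 10"):
            fit_model("TPL", np.linspace(1, 5, 9), l_min=0.5)


class TestCohortSummary:
    def test_proportions(self):
        from termwalk import ModelSelection

        sels = []
        winners = ["TPL"] * 4 + ["BiExp"]
        for i, w in enumerate(winners):
            fits = tuple(fits_from_nll([100.0, 110.0, 120.0]))
            sels.append(
                ModelSelection(
                    id=f"q{i}",
                    fits=fits,
                    weights=np.array([1.0, 0.0, 0.0]),
                    winner=w,
                    decisive=True,
                )
            )
        grouping = {f"q{i}": ("queen", 1) for i in range(5)}
        table = cohort_summary(sels, grouping)
        assert len(table) == 1
        row = table.iloc[0]
        assert row["prop_TPL"] == pytest.approx(0.8)
        assert row["prop_BiExp"] == pytest.approx(0.2)
        assert row["prop_TPL"] + row["prop_TE"] + row["prop_BiExp"] == pytest.approx(1.0)

    def test_single_individual(self):
        sel = select_model(fits_from_nll([100.0, 120.0, 130.0]), id="solo")
        table = cohort_summary([sel], {"solo": ("worker", 1)})
        assert table.iloc[0]["prop_TPL"] == 1.0
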