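"""BLUPs, allele effects, heritabilities and breeding values."""

import numpy as np
import pytest

import polyqtl as pq
from polyqtl.effects import breeding_value_correlations
from polyqtl.search import profile_qtl
from polyqtl.simulate import z_from_states


@pytest.fixture(scope="module")
def fitted_model(grid298):
    """A two-QTL trait with its profiled REMIM model."""
    spec = pq.TraitSpec(qtl=((1, 30.0, 0.9), (3, 80.0, 0.6)))
    truth = pq.simulate_trait(grid298, spec, rng=21)
    idx = [grid298.map.locate(1, 30.0), grid298.map.locate(3, 80.0)]
    prof = profile_qtl(truth.y, grid298, idx)
    return truth.y, prof.model


def test_blup_identities(grid298, fitted_model):
    """g_hat = Z u_hat and sum(u_hat) = 0 to 1e-8; ditto per-parent effects."""
    y, model = fitted_model
    eff = pq.compute_blups(y, grid298, model)
    for j, q in enumerate(model.qtl):
        Z = z_from_states(_states(grid298, q.index), grid298.space)
        assert np.allclose(eff.g_hat[j], Z @ eff.u_hat[j], atol=1e-8)
        assert abs(eff.u_hat[j].sum()) < 1e-8
        alle = eff.allele.iloc[j].to_numpy()
        assert abs(alle[:6].sum()) < 1e-8 and abs(alle[6:].sum()) < 1e-8


def _states(grid, q):
    """Recover one-hot states from the dosage factor of a hard-Z grid."""
    S = grid.space.incidence()
    hits = np.argmax(grid.X[q] @ S.T, axis=1)
    assert np.allclose(grid.X[q], S[hits])
    return hits


def test_zero_variance_qtl_has_zero_blups(grid298, fitted_model):
    y, model = fitted_model
    import copy
    model2 = copy.deepcopy(model)
    model2.qtl[1].sigma2_q = 0.0
    eff = pq.compute_blups(y, grid298, model2)
    assert np.allclose(eff.u_hat[1], 0.0)
    assert np.allclose(eff.g_hat[1], 0.0)


def test_allele_effects_zero_input(space6):
    assert np.allclose(pq.allele_effects(np.zeros(space6.n_states), space6), 0.0)


def test_allele_effects_recover_additive_truth(grid298):
    """u built from known allele effects is recovered with r > 0.95."""
    space = grid298.space
    rng = np.random.default_rng(31)
    alpha = rng.standard_normal(12) * 0.4
    alpha[:6] -= alpha[:6].mean()
    alpha[6:] -= alpha[6:].mean()
    q = grid298.map.locate(2, 40.0)
    g = grid298.X[q] @ alpha  # additive genetic values
    y = g + rng.standard_normal(grid298.n) * np.sqrt(g.var())
    prof = profile_qtl(y, grid298, [q])
    eff = pq.compute_blups(y, grid298, prof.model)
    est = eff.allele.iloc[0].to_numpy()
    r = np.corrcoef(est, alpha)[0, 1]
    assert r > 0.95


def test_summary_heritability_recovery(grid298):
    """Single h^2 = 0.3 QTL: median estimated h^2 within [0.2, 0.4], 50 reps."""
    sigma2_q = 0.3 / 0.7
    q = grid298.map.locate(1, 80.0)
    rng = np.random.default_rng(41)
    spec = pq.TraitSpec(qtl=((1, 80.0, sigma2_q),))
    h2 = []
    for _ in range(50):
        y = pq.simulate_trait(grid298, spec, rng).y
        model = profile_qtl(y, grid298, [q]).model
        h2.append(pq.summarize_model(model).table["h2_pct"].iloc[0] / 100.0)
    assert 0.2 <= np.median(h2) <= 0.4


def test_summary_invariants(grid298, fitted_model):
    y, model = fitted_model
    summary = pq.summarize_model(model)
    tab = summary.table
    assert len(tab) == 2
    assert np.all(tab["sigma2_q"] >= 0)
    assert tab["h2_pct"].sum() <= 100.0
    expect = 100.0 * tab["sigma2_q"] / summary.total_variance
    assert np.allclose(tab["h2_pct"], expect)


def test_empty_model_summary():
    model = pq.reml_fit(np.arange(10.0), [])
    summary = pq.summarize_model(model)
    assert summary.n_qtl == 0
    assert summary.sigma2 > 0


class TestBreedingValues:
    def test_single_qtl_equals_g_hat(self, grid298, fitted_model):
        y, model = fitted_model
        import copy
        single = copy.deepcopy(model)
        del single.qtl[1]
        eff = pq.compute_blups(y, grid298, single)
        bv = pq.breeding_values(eff)
        assert np.allclose(bv["breeding_value"].to_numpy(), eff.g_hat[0])

    def test_zero_variance_qtl_leaves_totals_unchanged(self, grid298,
                                                       fitted_model):
        y, model = fitted_model
        import copy
        model2 = copy.deepcopy(model)
        model2.qtl[1].sigma2_q = 0.0
        bv1 = pq.breeding_values(pq.compute_blups(y, grid298, model2))
        single = copy.deepcopy(model2)
        del single.qtl[1]
        bv2 = pq.breeding_values(pq.compute_blups(y, grid298, single))
        assert np.allclose(bv1["breeding_value"], bv2["breeding_value"])

    def test_requires_a_qtl(self):
        from polyqtl.effects import EffectsTable
        import pandas as pd
        empty = EffectsTable(u_hat=np.zeros((0, 4)), g_hat=np.zeros((0, 3)),
                             allele=pd.DataFrame(), individuals=["a", "b", "c"])
        with pytest.raises(ValueError):
            pq.breeding_values(empty)

    def test_shared_qtl_traits_correlate_more(self, grid298):
        """Breeding values correlate across traits sharing a QTL effect."""
        rng = np.random.default_rng(51)
        qa = grid298.map.locate(1, 50.0)
        qb = grid298.map.locate(3, 50.0)
        shared = pq.simulate_trait(
            grid298, pq.TraitSpec(qtl=((1, 50.0, 0.9),)), rng).genetic_values[0]
        ya = shared + rng.standard_normal(grid298.n)
        yb = shared + rng.standard_normal(grid298.n)
        yc = pq.simulate_trait(
            grid298, pq.TraitSpec(qtl=((3, 50.0, 0.9),)), rng).y
        tables = {
            "A": pq.compute_blups(ya, grid298, profile_qtl(ya, grid298, [qa]).model),
            "B": pq.compute_blups(yb, grid298, profile_qtl(yb, grid298, [qa]).model),
            "C": pq.compute_blups(yc, grid298, profile_qtl(yc, grid298, [qb]).model),
        }
        corr = breeding_value_correlations(tables)
        assert corr.loc["A", "B"] > corr.loc["A", "C"]
        assert corr.loc["A", "B"] > 0.5
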