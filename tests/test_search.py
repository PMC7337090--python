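"""Forward-backward QTL search, resampling thresholds, LOP profiles."""

import numpy as np
import pytest

import polyqtl as pq
from polyqtl.search import ScanContext, forward_search, optimize_model, profile_qtl


def test_config_validation():
    with pytest.raises(ValueError):
        pq.SearchConfig(forward_alpha=0.05, backward_alpha=0.20)
    with pytest.raises(ValueError):
        pq.SearchConfig(window_cM=-1.0)


def test_thresholds_shrink_with_alpha(remim_thresholds):
    assert remim_thresholds[0.05] < remim_thresholds[0.20]
    assert 0.0 < remim_thresholds[0.05] < 1.0


def test_threshold_calibration(grid298, remim_thresholds):
    """A null genome scan crosses the level-alpha threshold ~alpha of the time."""
    rng = np.random.default_rng(55)
    n_rep = 200
    hits = 0
    for _ in range(n_rep):
        ctx = ScanContext(rng.standard_normal(grid298.n), grid298, [])
        min_p = min(ctx.score_test(r)[1] for r in range(grid298.n_positions))
        hits += min_p < remim_thresholds[0.05]
    se = np.sqrt(0.05 * 0.95 / n_rep)
    assert abs(hits / n_rep - 0.05) < 3 * se


def test_null_trait_gives_empty_model(grid298, remim_thresholds, search_config):
    y = np.random.default_rng(77).standard_normal(grid298.n)
    indices = forward_search(y, grid298, [], remim_thresholds[0.20], search_config)
    indices = optimize_model(y, grid298, indices, remim_thresholds[0.05],
                             search_config, repeat_forward=False)
    assert indices == []


def test_forward_detects_single_strong_qtl(grid298, remim_thresholds,
                                           search_config):
    """h^2 = 0.3 QTL found within 20 cM in >= 90% of 50 seeded replicates."""
    sigma2_q = 0.3 / 0.7  # h2 = 0.3 against residual 1
    rng = np.random.default_rng(88)
    spec = pq.TraitSpec(qtl=((2, 60.0, sigma2_q),))
    good = 0
    for _ in range(50):
        y = pq.simulate_trait(grid298, spec, rng).y
        idx = forward_search(y, grid298, [], remim_thresholds[0.20],
                             search_config)
        hits = [i for i in idx if grid298.map.lg[i] == 2
                and abs(grid298.map.pos[i] - 60.0) <= 20.0]
        good += len(hits) == 1 and len(idx) == len(hits) + sum(
            grid298.map.lg[i] != 2 or abs(grid298.map.pos[i] - 60.0) > 20.0
            for i in idx if i not in hits)
    assert good >= 45


def test_window_rule_separates_selections(grid298, remim_thresholds,
                                          search_config):
    y = pq.simulate_trait(
        grid298,
        pq.TraitSpec(qtl=((1, 20.0, 0.75), (1, 80.0, 0.75), (3, 50.0, 0.5))),
        rng=33).y
    idx = forward_search(y, grid298, [], remim_thresholds[0.20], search_config)
    for a in idx:
        for b in idx:
            if a != b and grid298.map.lg[a] == grid298.map.lg[b]:
                assert abs(grid298.map.pos[a] - grid298.map.pos[b]) > 20.0


def test_linked_qtl_60cm_apart_both_retained(grid298, remim_thresholds,
                                             search_config):
    """Two QTL on one LG, 60 cM apart, survive optimization as two QTL."""
    y = pq.simulate_trait(
        grid298, pq.TraitSpec(qtl=((2, 30.0, 0.75), (2, 90.0, 0.75))), rng=44).y
    idx = forward_search(y, grid298, [], remim_thresholds[0.20], search_config)
    idx = optimize_model(y, grid298, idx, remim_thresholds[0.05], search_config,
                         repeat_forward=False)
    on_lg2 = [grid298.map.pos[i] for i in idx if grid298.map.lg[i] == 2]
    assert len(on_lg2) == 2
    assert min(abs(p - 30.0) for p in on_lg2) <= 20.0
    assert min(abs(p - 90.0) for p in on_lg2) <= 20.0


def test_optimize_is_idempotent(grid298, remim_thresholds, search_config):
    y = pq.simulate_trait(
        grid298, pq.TraitSpec(qtl=((1, 40.0, 0.9),)), rng=66).y
    idx = forward_search(y, grid298, [], remim_thresholds[0.20], search_config)
    once = optimize_model(y, grid298, idx, remim_thresholds[0.05],
                          search_config, repeat_forward=False)
    twice = optimize_model(y, grid298, list(once), remim_thresholds[0.05],
                           search_config, repeat_forward=False)
    assert once == twice


def test_search_is_deterministic(grid298, remim_thresholds, search_config):
    y = pq.simulate_trait(
        grid298, pq.TraitSpec(qtl=((3, 70.0, 0.75),)), rng=99).y
    p1 = pq.remim_search(y, grid298, remim_thresholds, search_config)
    p2 = pq.remim_search(y, grid298, remim_thresholds, search_config)
    assert [q.index for q in p1.model.qtl] == [q.index for q in p2.model.qtl]
    assert np.array_equal(p1.p_value, p2.p_value)


@pytest.fixture(scope="module")
def fitted(grid298, remim_thresholds, search_config):
    y = pq.simulate_trait(
        grid298,
        pq.TraitSpec(qtl=((1, 30.0, 0.75), (2, 60.0, 0.5))), rng=111).y
    prof = pq.remim_search(y, grid298, remim_thresholds, search_config,
                           repeat_forward=False)
    return y, prof


class TestProfile:
    def test_retained_qtl_beat_backward_threshold(self, fitted,
                                                  remim_thresholds):
        _, prof = fitted
        for q in prof.model.qtl:
            assert q.p_value < remim_thresholds[0.05]

    def test_supports_cover_model_positions_and_nest(self, fitted, grid298):
        _, prof = fitted
        for q in prof.model.qtl:
            lo, hi = q.support
            assert lo <= q.pos_cM <= hi
            wider = pq.lop_support_interval(prof, q.index, 3.0)
            assert wider[0] <= lo and hi <= wider[1]

    def test_empty_model_profile_is_single_qtl_scan(self, grid298):
        y = np.random.default_rng(5).standard_normal(grid298.n)
        prof = profile_qtl(y, grid298, [])
        ctx = ScanContext(y, grid298, [])
        direct = np.array([ctx.score_test(r) for r in range(grid298.n_positions)])
        assert np.allclose(prof.score, direct[:, 0], atol=1e-10)
        assert np.allclose(prof.p_value, direct[:, 1], rtol=1e-10)

    def test_peaks_near_simulated_qtl(self, fitted, grid298):
        _, prof = fitted
        positions = [(q.lg, q.pos_cM) for q in prof.model.qtl]
        for lg, true_pos in [(1, 30.0), (2, 60.0)]:
            assert any(l == lg and abs(p - true_pos) <= 20.0
                       for l, p in positions)


def test_pipeline_type_one_error(grid298, remim_thresholds, search_config):
    """Full search on null traits declares any QTL at most ~alpha of the time."""
    rng = np.random.default_rng(123)
    n_rep = 100
    fp_forward = 0
    fp_final = 0
    for _ in range(n_rep):
        y = rng.standard_normal(grid298.n)
        idx = forward_search(y, grid298, [], remim_thresholds[0.20],
                             search_config)
        fp_forward += bool(idx)
        idx = optimize_model(y, grid298, idx, remim_thresholds[0.05],
                             search_config, repeat_forward=False)
        fp_final += bool(idx)
    se = np.sqrt(0.05 * 0.95 / n_rep)
    assert fp_final / n_rep <= 0.05 + 3 * se
    # backward elimination prunes most permissive forward picks
    assert fp_final <= fp_forward
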