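"""Scalar stages of the fuzzy system: ROAD, impulsivity, similarity, rules,
defuzzification and the weighted-average update."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad

from fgict import (
    FilterParams,
    RuleActivation,
    defuzzify_weight,
    impulsivity,
    neighborhood,
    pixel_update,
    road,
    rule_activations,
    similarity,
)
from fgict.reference import aggregate_consequents, defuzzify_weight_polygon

P3 = 1.96 / 255.0
P4 = 0.9

unit = st.floats(min_value=0.0, max_value=1.0, allow_nan=False)


# --- ROAD -------------------------------------------------------------------

def test_road_flat_window_is_zero():
    neigh = neighborhood(np.full((3, 3), 0.5), 1, 1, 3)
    assert road(neigh, 4) == 0.0


def test_road_single_impulse():
    # centre 0.9 in a flat 0.5 background: all 8 differences are 0.4,
    # the 4 smallest sum to 1.6
    img = np.full((3, 3), 0.5)
    img[1, 1] = 0.9
    assert road(neighborhood(img, 1, 1, 3), 4) == pytest.approx(1.6)


def test_road_sorts_differences():
    # neighbour diffs {0.1..0.8}: brute-force sort-and-sum of the 4 smallest
    img = np.zeros((3, 3))
    diffs = [0.5, 0.3, 0.8, 0.1, 0.7, 0.2, 0.6, 0.4]
    img.reshape(-1)[[0, 1, 2, 3, 5, 6, 7, 8]] = diffs
    expected = sum(sorted(diffs)[:4])
    assert road(neighborhood(img, 1, 1, 3), 4) == pytest.approx(expected)
    assert expected == pytest.approx(1.0)


def test_road_truncated_border_uses_available():
    # corner pixel has only 3 neighbours; r=4 falls back to all of them
    img = np.arange(9.0).reshape(3, 3)
    neigh = neighborhood(img, 0, 0, 3)
    assert neigh.window_size == 4
    assert road(neigh, 4) == pytest.approx(1.0 + 3.0 + 4.0)


# --- impulsivity ------------------------------------------------------------

@pytest.mark.parametrize("r_val, expected", [(0.1, 0.0), (0.9, 1.0), (0.5, 0.5), (0.0, 0.0), (2.0, 1.0)])
def test_impulsivity_ramp(r_val, expected):
    assert impulsivity(r_val, 0.1, 0.9) == pytest.approx(expected)


# --- similarity -------------------------------------------------------------

@pytest.mark.parametrize(
    "L1, expected",
    [
        (0.0, (1.0, 0.0, 0.0)),
        (2.5 * P3, (0.5, 1.0, 0.5)),
        (1.5 * P3, (5.0 / 6.0, 0.5, 1.0 / 6.0)),
        (4.0 * P3, (0.0, 0.0, 1.0)),
        (P3, (1.0, 0.0, 0.0)),
    ],
)
def test_similarity_memberships(L1, expected):
    assert similarity(L1, P3) == pytest.approx(expected)


@settings(deadline=None, max_examples=200)
@given(st.floats(min_value=0.0, max_value=0.2, allow_nan=False))
def test_similarity_negation_identity(L1):
    """mu_H + mu_L == 1 identically, and every degree lies in [0,1]."""
    mu_h, mu_m, mu_l = similarity(L1, P3)
    assert mu_h + mu_l == pytest.approx(1.0, abs=1e-15)
    for m in (mu_h, mu_m, mu_l):
        assert 0.0 <= m <= 1.0


# --- rules ------------------------------------------------------------------

def test_rule_impulsive_center_moderate_neighbor():
    # clean neighbour of an impulse with moderate similarity -> moderate weight
    act = rule_activations(1.0, 0.0, 0.0, 1.0, 0.0)
    assert (act.alpha_M, act.alpha_H, act.alpha_L) == (1.0, 0.0, 0.0)


def test_rule_clean_similar_pair_fires_high():
    act = rule_activations(0.0, 0.0, 1.0, 0.0, 0.0)
    assert (act.alpha_M, act.alpha_H, act.alpha_L) == (0.0, 1.0, 0.0)


@settings(deadline=None, max_examples=100)
@given(unit, unit)
def test_rule_impulsive_neighbor_always_low(delta_i, mu_h):
    """An impulsive neighbour gets a fully activated low consequent."""
    act = rule_activations(delta_i, 1.0, mu_h, 0.0, 1.0 - mu_h)
    assert act.alpha_L == 1.0


@settings(deadline=None, max_examples=200)
@given(unit, unit, unit)
def test_rule_activations_bounded(delta_i, delta_j, mu_h):
    act = rule_activations(delta_i, delta_j, mu_h, 0.3, 1.0 - mu_h)
    for a in (act.alpha_M, act.alpha_H, act.alpha_L):
        assert 0.0 <= a <= 1.0


# --- defuzzification --------------------------------------------------------

def test_cog_pure_consequents():
    assert defuzzify_weight(RuleActivation(1, 0, 0), P4) == pytest.approx(0.5)
    assert defuzzify_weight(RuleActivation(0, 1, 0), P4) == pytest.approx((2 + P4) / 3)
    assert defuzzify_weight(RuleActivation(0, 0, 1), P4) == pytest.approx((1 - P4) / 3)
    assert defuzzify_weight(RuleActivation(0, 0, 0), P4) == 0.0


def test_cog_matches_numeric_quadrature_on_grid():
    """Closed-form COG equals adaptive quadrature of the aggregated polygon
    over the full 5x5x5 activation grid, and the weight stays inside the
    aggregate's support."""
    levels = [0.0, 0.25, 0.5, 0.75, 1.0]
    for a_m in levels:
        for a_h in levels:
            for a_l in levels:
                act = RuleActivation(a_m, a_h, a_l)
                w = defuzzify_weight(act, P4)
                L = aggregate_consequents(a_l, a_m, a_h, P4)
                area, _ = quad(L, 0, 1, limit=200)
                moment, _ = quad(lambda x: x * L(x), 0, 1, limit=200)
                if area == 0.0:
                    assert w == 0.0
                    continue
                assert w == pytest.approx(moment / area, abs=1e-6)
                support = [x / 2000 for x in range(2001) if L(x / 2000) > 0]
                assert support[0] <= w <= support[-1]


# activation levels: exactly zero or bounded away from the underflow regime,
# where the polygon oracle's truncation breakpoint c*(1-alpha) is no longer
# representable distinctly from the support endpoint
level = st.one_of(st.just(0.0), st.floats(min_value=1e-6, max_value=1.0))


@settings(deadline=None, max_examples=150)
@given(level, level, level, st.floats(min_value=0.55, max_value=0.95))
def test_cog_routes_agree(a_m, a_h, a_l, p4):
    """Closed-form, compiled, and polygon-integration implementations of the
    COG agree to near machine precision."""
    from fgict._engine import cog_weight

    w1 = defuzzify_weight(RuleActivation(a_m, a_h, a_l), p4)
    w2 = defuzzify_weight_polygon(a_l, a_m, a_h, p4)
    w3 = cog_weight(a_l, a_m, a_h, p4)
    # 1e-9: near-zero activations cost a few digits to cancellation in the
    # area/moment ratio; both routes are exact integrals analytically
    assert w1 == pytest.approx(w2, abs=1e-9)
    assert w1 == pytest.approx(w3, abs=1e-12)
    assert 0.0 <= w1 <= 1.0


# --- weighted average -------------------------------------------------------

def test_pixel_update_mean_and_degenerate():
    img = np.array([[0.2, 0.4], [0.6, 0.2]])
    neigh = neighborhood(img, 0, 0, 3)
    vals = {0.2, 0.4, 0.6}
    assert set(np.round(neigh.neighbor_values, 10)) == vals
    assert pixel_update(neigh, [1.0] * 4, "base") == pytest.approx(np.mean(img))
    assert pixel_update(neigh, [0.0] * 4, "base") == pytest.approx(0.2)  # centre kept


def test_pixel_update_weighted():
    neigh = neighborhood(np.array([[1.0, 0.0]]), 0, 0, 3)
    assert pixel_update(neigh, [0.9, 0.1], "base") == pytest.approx(0.9)


def test_pixel_update_skip_center():
    neigh = neighborhood(np.array([[1.0, 0.0]]), 0, 0, 3)
    assert pixel_update(neigh, [0.9, 0.1], "skip_q") == pytest.approx(0.0)


def test_filter_params_validation():
    with pytest.raises(ValueError):
        FilterParams(n=4)
    with pytest.raises(ValueError):
        FilterParams(p1=0.5, p2=0.4)
    with pytest.raises(ValueError):
        FilterParams(p4=0.4)
    with pytest.raises(ValueError):
        FilterParams(variant="turbo")
    with pytest.raises(ValueError):
        FilterParams(stop="max_psnr", max_iterations=0)
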