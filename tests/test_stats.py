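"""Factorial statistics: ANOVA vs closed-form oracles, prechecks, LSD
letters vs exhaustive pairwise comparison."""

import itertools

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from nbudget import (DesignError, anova_nway, lsd_groups, lsd_threshold,
                     precheck)


def two_level_data(rng, n=6, delta=1.0):
    a = rng.normal(0.0, 1.0, n)
    b = rng.normal(delta, 1.0, n)
    return pd.DataFrame({"g": ["a"] * n + ["b"] * n,
                         "y": np.concatenate([a, b])})


def test_constant_response_gives_zero_f():
    data = pd.DataFrame({"g": list("aabb"), "h": list("xyxy"), "y": [5.0] * 4})
    tab = anova_nway(data, "y", ["g", "h"], max_interaction_order=1)
    assert tab.term("g")["F"] == 0.0 and tab.term("g")["p"] == 1.0
    assert tab.term("h")["sig"] == "ns"


def test_one_factor_f_equals_t_squared():
    rng = np.random.default_rng(11)
    for _ in range(10):
        data = two_level_data(rng, n=5, delta=rng.uniform(0, 2))
        tab = anova_nway(data, "y", ["g"])
        t, p = scipy.stats.ttest_ind(data.y[data.g == "a"], data.y[data.g == "b"])
        assert tab.term("g")["F"] == pytest.approx(t ** 2, rel=1e-9)
        assert tab.term("g")["p"] == pytest.approx(p, rel=1e-9)


def brute_force_ss(data, factors):
    """Balanced-design sums of squares from cell and marginal means."""
    grand = data.y.mean()
    n = len(data)
    ss = {}
    for order in range(1, len(factors) + 1):
        for combo in itertools.combinations(factors, order):
            marg = data.groupby(list(combo)).y.mean()
            reps = n / marg.size
            raw = reps * ((marg - grand) ** 2).sum()
            inner = sum(ss[c] for o in range(1, order)
                        for c in itertools.combinations(combo, o))
            ss[combo] = raw - inner
    return ss


def test_2x2x2_ss_matches_bruteforce_cell_means():
    rng = np.random.default_rng(3)
    levels = [("lo", "hi")] * 3
    rows = []
    for a, b, c in itertools.product(*levels):
        effect = (a == "hi") * 2.0 + (b == "hi") * 1.0 + (a == b == "hi") * 0.5
        for _ in range(3):
            rows.append((a, b, c, effect + rng.normal(0, 0.3)))
    data = pd.DataFrame(rows, columns=["A", "B", "C", "y"])
    tab = anova_nway(data, "y", ["A", "B", "C"])
    oracle = brute_force_ss(data, ["A", "B", "C"])
    for combo, ss in oracle.items():
        term = ":".join(combo)
        assert tab.term(term)["sum_sq"] == pytest.approx(ss, abs=1e-9), term
    total = ((data.y - data.y.mean()) ** 2).sum()
    assert tab.table["sum_sq"].sum() == pytest.approx(total, rel=1e-12)


def test_f_invariant_under_shift_and_scale():
    rng = np.random.default_rng(5)
    data = two_level_data(rng, n=6, delta=1.2)
    f0 = anova_nway(data, "y", ["g"]).term("g")["F"]
    shifted = data.assign(y=data.y + 100.0)
    scaled = data.assign(y=data.y * 7.5)
    assert anova_nway(shifted, "y", ["g"]).term("g")["F"] == pytest.approx(f0, rel=1e-9)
    assert anova_nway(scaled, "y", ["g"]).term("g")["F"] == pytest.approx(f0, rel=1e-9)


def test_design_errors():
    data = pd.DataFrame({"g": list("ab"), "y": [1.0, 2.0]})
    with pytest.raises(DesignError, match="error degrees of freedom"):
        anova_nway(data, "y", ["g"])
    with pytest.raises(DesignError, match="levels"):
        anova_nway(pd.DataFrame({"g": ["a"] * 4, "y": range(4)}), "y", ["g"])


def test_unbalanced_warns_and_uses_type2():
    rng = np.random.default_rng(9)
    data = two_level_data(rng, n=6)
    data = data.iloc[:-1]
    with pytest.warns(UserWarning, match="unbalanced"):
        tab = anova_nway(data, "y", ["g"])
    assert np.isfinite(tab.term("g")["F"])


def test_precheck_identical_groups():
    data = pd.DataFrame({"g": list("aaabbb"), "y": [1.0, 2.0, 3.0] * 2})
    rep = precheck(data, "y", ["g"])
    assert rep.levene_stat == pytest.approx(0.0)
    assert rep.shapiro_w is not None and rep.shapiro_w <= 1.0


def test_precheck_not_testable():
    data = pd.DataFrame({"g": ["a", "b"], "y": [1.0, 1.0]})
    rep = precheck(data, "y", ["g"])
    assert rep.shapiro_w is None and rep.levene_stat is None
    assert any("not testable" in n for n in rep.notes)


def test_levene_detects_heteroscedasticity():
    """SD ratio 5 at n=30/group: Levene rejects at 0.05 in >=90% of 200
    seeded simulations."""
    rng = np.random.default_rng(1234)
    hits = 0
    for _ in range(200):
        data = pd.DataFrame({
            "g": ["a"] * 30 + ["b"] * 30,
            "y": np.concatenate([rng.normal(0, 1, 30), rng.normal(0, 5, 30)])})
        if precheck(data, "y", ["g"]).levene_p < 0.05:
            hits += 1
    assert hits >= 180


def pairwise_letter_oracle(means: dict, lsd: float):
    """Exhaustive pairwise test: for every pair, share-a-letter must equal
    |difference| <= LSD."""
    return {(a, b): abs(means[a] - means[b]) <= lsd
            for a, b in itertools.combinations(means, 2)}


def test_lsd_letters_forced_separation_and_ties():
    g = lsd_groups({"hi": 10.0, "lo": 0.0}, mse=1.0, error_df=10, n_per_cell=3)
    assert g.letters["hi"] == "a" and g.letters["lo"] == "b"
    g2 = lsd_groups({"x": 5.0, "y": 5.0, "z": 5.0}, mse=1.0, error_df=10,
                    n_per_cell=3)
    assert set(g2.letters.values()) == {"a"}


def test_protected_lsd_suppresses_separation():
    g = lsd_groups({"hi": 10.0, "lo": 0.0}, mse=1.0, error_df=10, n_per_cell=3,
                   omnibus_p=0.40)
    assert not g.protected_ok
    assert g.letters["hi"] == g.letters["lo"] == "a"


def test_lsd_threshold_formula():
    lsd = lsd_threshold(mse=2.0, error_df=12, n_per_cell=3, alpha=0.05)
    t = scipy.stats.t.ppf(0.975, 12)
    assert lsd == pytest.approx(t * np.sqrt(2 * 2.0 / 3))


def test_letters_match_pairwise_oracle_on_randomized_means():
    rng = np.random.default_rng(77)
    for trial in range(60):
        k = rng.integers(3, 7)
        means = {f"L{i}": float(rng.uniform(0, 10)) for i in range(k)}
        g = lsd_groups(means, mse=float(rng.uniform(0.2, 4.0)),
                       error_df=int(rng.integers(5, 30)), n_per_cell=3)
        oracle = pairwise_letter_oracle(means, g.lsd)
        for (a, b), same_expected in oracle.items():
            share = bool(set(g.letters[a]) & set(g.letters[b]))
            assert share == same_expected, (trial, a, b, means, g.lsd, g.letters)
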