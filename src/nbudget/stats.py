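"""Factorial treatment statistics: crossed fixed-effects ANOVA, residual
normality / variance-homogeneity prechecks, and protected LSD post hoc
comparisons with a compact letter display.

The ANOVA is a fixed-effects crossed model fit by OLS, with all factor
interactions up to a requested order; F for each term is MS(term) /
MS(error). Balanced designs use the sequential (Type I) decomposition,
which is then orthogonal and exact; unbalanced data fall back to Type II
with a warning. Significance tags follow the agronomic convention:
``**`` p < 0.01, ``*`` p < 0.05, ``ns`` otherwise.

LSD at level α with m replicates per cell is t(1−α/2, df_e)·√(2·MSE/m);
protected use runs the pairwise comparisons only after a significant
omnibus F. With means sorted descending, the mutually-non-different sets
are contiguous runs, so letters are assigned to maximal runs whose
max−min spread is within the LSD (insert-and-absorb collapses to this
for interval overlap structures); two levels then share a letter exactly
when their difference is within the LSD.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm

from .core import DesignError, NbudgetError, ValidationError


def significance_tag(p: float) -> str:
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


@dataclass(frozen=True)
class AnovaTable:
    """Per-term df, SS, MS, F, p and significance tag, plus the error row."""

    table: pd.DataFrame  # index: term names + "Residual"

    def term(self, name: str) -> pd.Series:
        return self.table.loc[name]

    @property
    def mse(self) -> float:
        return float(self.table.loc["Residual", "mean_sq"])

    @property
    def error_df(self) -> int:
        return int(self.table.loc["Residual", "df"])


def _formula(names: Sequence[str], max_order: int) -> str:
    # internal sanitized names, so factor columns can never shadow patsy
    # builtins (C, Q, ...) or contain awkward characters
    terms = []
    for order in range(1, max_order + 1):
        for combo in itertools.combinations(names, order):
            terms.append(":".join(f"C({f})" for f in combo))
    return "_resp_ ~ " + " + ".join(terms)


def _is_balanced(data: pd.DataFrame, factors: Sequence[str]) -> bool:
    counts = data.groupby(list(factors), sort=False).size()
    full = np.prod([data[f].nunique() for f in factors])
    return len(counts) == full and counts.nunique() == 1


def anova_nway(data: pd.DataFrame, response: str, factors: Sequence[str],
               max_interaction_order: int | None = None) -> AnovaTable:
    """Crossed fixed-effects ANOVA of ``response`` on categorical ``factors``.

    ``max_interaction_order`` defaults to the full factorial (all
    interactions). Requires ≥2 levels per factor and positive error df.
    """
    factors = list(factors)
    missing = [f for f in factors if f not in data.columns]
    if missing or response not in data.columns:
        raise ValidationError(
            f"unknown column(s): {missing + ([response] if response not in data.columns else [])}")
    for f in factors:
        if data[f].nunique() < 2:
            raise DesignError(f"factor {f!r} needs >= 2 levels")
    if max_interaction_order is None:
        max_interaction_order = len(factors)
    max_interaction_order = min(max_interaction_order, len(factors))
    names = [f"_f{i}_" for i in range(len(factors))]
    work = data[[response] + factors].copy()
    work.columns = ["_resp_"] + names
    model = smf.ols(_formula(names, max_interaction_order), data=work).fit()
    if model.df_resid < 1:
        raise DesignError("zero error degrees of freedom: add replicates "
                          "or reduce the interaction order")
    balanced = _is_balanced(data, factors)
    if not balanced:
        warnings.warn("unbalanced design: using Type II sums of squares",
                      stacklevel=2)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # F=0/p=NaN when MSE=0
        raw = anova_lm(model, typ=1 if balanced else 2)
    tab = raw.rename(columns={"sum_sq": "sum_sq", "df": "df", "F": "F",
                              "PR(>F)": "p"}).copy()
    tab["mean_sq"] = tab["sum_sq"] / tab["df"]
    # zero residual variance: every F-ratio of a zero-SS term is 0, p = 1
    if tab.loc["Residual", "sum_sq"] == 0:
        nonres = tab.index != "Residual"
        zero = nonres & (tab["sum_sq"].abs() < 1e-12)
        tab.loc[zero, "F"] = 0.0
        tab.loc[zero, "p"] = 1.0
    tab.index = [_clean_term(t, names, factors) for t in tab.index]
    tab["sig"] = [significance_tag(p) if np.isfinite(p) else ""
                  for p in tab["p"].fillna(np.inf)]
    return AnovaTable(tab[["df", "sum_sq", "mean_sq", "F", "p", "sig"]])


def _clean_term(term: str, names: Sequence[str], factors: Sequence[str]) -> str:
    if term == "Residual":
        return term
    parts = [p.removeprefix("C(").removesuffix(")") for p in term.split(":")]
    return ":".join(factors[names.index(p)] for p in parts)


@dataclass(frozen=True)
class PrecheckReport:
    """Shapiro–Wilk on residuals and Levene across cells; advisory only."""

    shapiro_w: float | None
    shapiro_p: float | None
    levene_stat: float | None
    levene_p: float | None
    notes: tuple[str, ...] = ()

    @property
    def normal_ok(self) -> bool | None:
        return None if self.shapiro_p is None else self.shapiro_p >= 0.05

    @property
    def homoscedastic_ok(self) -> bool | None:
        return None if self.levene_p is None else self.levene_p >= 0.05


def precheck(data: pd.DataFrame, response: str,
             factors: Sequence[str]) -> PrecheckReport:
    """Normality (Shapiro–Wilk on cell residuals) and homogeneity (Levene,
    median-centered) prechecks. Insufficient data marks a test "not
    testable" rather than failing."""
    factors = list(factors)
    cells = [g[response].to_numpy(dtype=float)
             for _, g in data.groupby(factors, sort=False)]
    notes: list[str] = []
    resid = np.concatenate([c - c.mean() for c in cells])
    sw = sp = None
    if resid.size >= 3 and np.ptp(resid) > 0:
        w, p = scipy.stats.shapiro(resid)
        sw, sp = float(w), float(p)
    else:
        notes.append("normality not testable (<3 residuals or zero spread)")
    ls = lp = None
    multi = [c for c in cells if c.size >= 2]
    if len(multi) >= 2:
        stat, p = scipy.stats.levene(*multi, center="median")
        if np.isfinite(stat):
            ls, lp = float(stat), float(p)
        else:
            ls, lp = 0.0, 1.0  # identical groups: no dispersion to compare
    else:
        notes.append("homogeneity not testable (<2 groups with >=2 values)")
    return PrecheckReport(sw, sp, ls, lp, tuple(notes))


@dataclass(frozen=True)
class LsdGrouping:
    """Per-level means with compact letters; shares-a-letter ⇔ difference
    within the LSD at alpha."""

    means: "pd.Series"  # index: level, descending mean order
    letters: Mapping[object, str]
    lsd: float
    alpha: float
    protected_ok: bool = True  # False when the omnibus F was not significant

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame({"mean": self.means,
                             "letters": [self.letters[k] for k in self.means.index]})


_ALPHABET = "abcdefghijklmnopqrstuvwxyz"


def lsd_threshold(mse: float, error_df: int, n_per_cell: int,
                  alpha: float = 0.05) -> float:
    """Fisher's least significant difference t(1−α/2, df)·√(2·MSE/n)."""
    if mse <= 0:
        raise ValidationError(f"MSE must be > 0, got {mse}")
    if error_df < 1:
        raise DesignError(f"error df must be >= 1, got {error_df}")
    t = scipy.stats.t.ppf(1 - alpha / 2, error_df)
    return float(t * np.sqrt(2 * mse / n_per_cell))


def lsd_groups(means: Mapping[object, float], mse: float, error_df: int,
               n_per_cell: int, alpha: float = 0.05,
               omnibus_p: float | None = None) -> LsdGrouping:
    """Compact letter display for level means under the LSD criterion.

    When ``omnibus_p`` is given and not significant at ``alpha``, the
    protected-LSD convention applies: no pairwise separation is claimed
    and every level shares the letter "a".
    """
    s = pd.Series(dict(means), dtype=float).sort_values(ascending=False)
    lsd = lsd_threshold(mse, error_df, n_per_cell, alpha)
    if omnibus_p is not None and omnibus_p >= alpha:
        return LsdGrouping(means=s, letters={k: "a" for k in s.index},
                           lsd=lsd, alpha=alpha, protected_ok=False)
    values = s.to_numpy()
    k = len(values)
    # maximal contiguous runs of mutually-non-different levels (means sorted
    # descending, so non-difference is an interval relation); the run end
    # j(i) is nondecreasing in i, so run i is maximal iff it extends j(i-1)
    maximal: list[tuple[int, int]] = []
    for i in range(k):
        j = i
        while j + 1 < k and values[i] - values[j + 1] <= lsd:
            j += 1
        if not maximal or j > maximal[-1][1]:
            maximal.append((i, j))
    letters: dict[object, list[str]] = {key: [] for key in s.index}
    for letter, (i, j) in zip(_ALPHABET, maximal):
        for idx in range(i, j + 1):
            letters[s.index[idx]].append(letter)
    return LsdGrouping(means=s, letters={k_: "".join(v) for k_, v in letters.items()},
                       lsd=lsd, alpha=alpha)


def anova_report(table: AnovaTable) -> pd.DataFrame:
    """Tidy per-term report frame (term, df, SS, MS, F, p, tag)."""
    out = table.table.reset_index(names="term")
    return out
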