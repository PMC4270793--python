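"""Comparative statistics for tropism frequencies and densities.

Implements the study-style battery: pooled two-sample proportion tests with
Bonferroni correction and compact-letter grouping, Fisher's exact test as the
fallback when zero frequencies preclude a logistic fit, logistic and linear
partitioning of host-background versus bacterial-strain effects, k-group
chi-square, pairwise t-test lettering for densities, and correlation of paired
male/female tropism frequencies.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TestResult",
    "FactorPartition",
    "FactorPartitionResult",
    "GroupLettering",
    "two_proportion_test",
    "fisher_exact",
    "bonferroni",
    "partition_frequency",
    "partition_density",
    "assign_letters",
    "chi_square_groups",
    "presence_correlation",
]

HOST_FACTOR = "host_background"
STRAIN_FACTOR = "wolbachia_strain"


@dataclass
class TestResult:
    """A test statistic with raw and (optionally) Bonferroni-adjusted p."""

    statistic: float
    p_value: float
    method: str
    p_adjusted: float | None = None
    df: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value must lie in [0, 1]")
        if self.p_adjusted is not None and self.p_adjusted < self.p_value - 1e-12:
            raise ValueError("adjusted p cannot be below the raw p")


def bonferroni(p: float, m: int) -> float:
    """Bonferroni-adjust a p value for m comparisons, capped at 1."""
    if m < 1:
        raise ValueError("number of comparisons must be >= 1")
    return min(1.0, m * p)


def two_proportion_test(
    k1: int,
    n1: int,
    k2: int,
    n2: int,
    continuity: bool = False,
) -> TestResult:
    """Two-sided pooled two-sample z-test for proportions.

    z = (p1 - p2) / sqrt(p(1-p)(1/n1 + 1/n2)) with p the pooled proportion;
    the optional Yates-style continuity correction subtracts
    (1/n1 + 1/n2)/2 from |p1 - p2|.
    """
    for k, n in ((k1, n1), (k2, n2)):
        if n < 1:
            raise ValueError("sample sizes must be >= 1")
        if not 0 <= k <= n:
            raise ValueError("require 0 <= k <= n")
    p1, p2 = k1 / n1, k2 / n2
    pooled = (k1 + k2) / (n1 + n2)
    var = pooled * (1 - pooled) * (1 / n1 + 1 / n2)
    if var == 0:
        return TestResult(statistic=0.0, p_value=1.0, method="two_proportion_z")
    diff = p1 - p2
    if continuity:
        correction = 0.5 * (1 / n1 + 1 / n2)
        diff = math.copysign(max(abs(diff) - correction, 0.0), diff)
    z = diff / math.sqrt(var)
    p = 2 * stats.norm.sf(abs(z))
    return TestResult(statistic=float(z), p_value=float(min(p, 1.0)), method="two_proportion_z")


def fisher_exact(table: Sequence[Sequence[int]]) -> TestResult:
    """Two-sided Fisher exact test on a 2x2 table.

    Two-sidedness follows the probability-mass rule: sum hypergeometric
    probabilities of all tables (with the observed margins) no more likely
    than the observed one.
    """
    arr = np.asarray(table)
    if arr.shape != (2, 2):
        raise ValueError("fisher_exact expects a 2x2 table")
    if np.any(arr < 0) or not np.issubdtype(arr.dtype, np.integer):
        if np.any(arr < 0) or not np.allclose(arr, np.round(arr)):
            raise ValueError("counts must be non-negative integers")
        arr = np.round(arr).astype(int)
    odds, p = stats.fisher_exact(arr, alternative="two-sided")
    return TestResult(statistic=float(odds), p_value=float(p), method="fisher_exact")


@dataclass
class FactorPartitionResult:
    """Per-factor effect estimates for host background and bacterial strain.

    ``params``/``bse``/``p_values`` map each factor to the coefficient of its
    non-reference level (treatment coding, reference = alphabetically first
    level).  Logistic coefficients are log odds ratios; linear coefficients
    are mean ratio shifts.  ``separation=True`` means the logistic likelihood
    had no finite maximizer (a zero cell in a factor-by-outcome table) and the
    per-factor p values come from Fisher exact tests on collapsed 2x2 tables.
    """

    params: dict[str, float]
    bse: dict[str, float]
    p_values: dict[str, float]
    model: str
    separation: bool = False
    reference_levels: dict[str, str] = field(default_factory=dict)
    nobs: int = 0

    def __post_init__(self) -> None:
        if set(self.params) != {HOST_FACTOR, STRAIN_FACTOR}:
            raise ValueError("exactly the two factors host/strain must be reported")
        if self.separation and self.model != "fisher_fallback":
            raise ValueError("separation implies the fisher_fallback model tag")

    def summary(self) -> str:
        lines = [
            "Host-vs-strain factor partition",
            "===============================",
            f"model: {self.model}    n = {self.nobs}"
            + ("    (separation detected)" if self.separation else ""),
            f"{'factor':<18}{'coef':>10}{'se':>10}{'p':>12}",
        ]
        for factor in (HOST_FACTOR, STRAIN_FACTOR):
            se = self.bse.get(factor)
            lines.append(
                f"{factor:<18}{self.params[factor]:>10.4f}"
                + (f"{se:>10.4f}" if se is not None and math.isfinite(se) else f"{'--':>10}")
                + f"{self.p_values[factor]:>12.4g}"
            )
        return "\n".join(lines)


def _validate_factors(df: pd.DataFrame, response: str) -> pd.DataFrame:
    for col in (HOST_FACTOR, STRAIN_FACTOR, response):
        if col not in df.columns:
            raise ValueError(f"records must provide a {col!r} column")
    df = df[[HOST_FACTOR, STRAIN_FACTOR, response]].dropna()
    for factor in (HOST_FACTOR, STRAIN_FACTOR):
        if df[factor].nunique() < 2:
            raise ValueError(f"factor {factor!r} has fewer than 2 levels")
    cross = pd.crosstab(df[HOST_FACTOR], df[STRAIN_FACTOR])
    # each strain confined to a single host (or vice versa) makes the two
    # factors collinear and the partition unidentifiable
    if ((cross > 0).sum(axis=0) == 1).all() or ((cross > 0).sum(axis=1) == 1).all():
        raise ValueError(
            "host and strain are completely confounded (each strain observed in "
            "only one host); the factor effects are not separable"
        )
    return df


def _design(df: pd.DataFrame) -> tuple[np.ndarray, list[str], dict[str, str]]:
    cols: list[np.ndarray] = [np.ones(len(df))]
    names = ["intercept"]
    refs: dict[str, str] = {}
    for factor in (HOST_FACTOR, STRAIN_FACTOR):
        levels = sorted(df[factor].astype(str).unique())
        refs[factor] = levels[0]
        for lvl in levels[1:]:
            cols.append((df[factor].astype(str) == lvl).to_numpy(float))
            names.append(f"{factor}[{lvl}]")
    return np.column_stack(cols), names, refs


class FactorPartition:
    """Model: partition tropism variation into host- and strain-level effects.

    Built from per-hub records with ``host_background`` and
    ``wolbachia_strain`` columns plus a response: a boolean ``tropism`` column
    (``kind="logistic"``) or a continuous ``ratio`` column (``kind="linear"``).
    ``fit`` returns a :class:`FactorPartitionResult`.
    """

    def __init__(self, data: pd.DataFrame, response: str, kind: str):
        if kind not in ("logistic", "linear"):
            raise ValueError("kind must be 'logistic' or 'linear'")
        self.kind = kind
        self.response = response
        self.data = _validate_factors(pd.DataFrame(data), response)

    @classmethod
    def from_dataframe(
        cls, data: pd.DataFrame, response: str = "tropism", kind: str = "logistic"
    ) -> "FactorPartition":
        return cls(data, response=response, kind=kind)

    def _factor_pvals(self, names: list[str], pvals: np.ndarray) -> dict[str, float]:
        # with >2 levels, report the smallest Bonferroni-adjusted level p per factor
        out: dict[str, float] = {}
        for factor in (HOST_FACTOR, STRAIN_FACTOR):
            idx = [i for i, nm in enumerate(names) if nm.startswith(f"{factor}[")]
            ps = pvals[idx]
            out[factor] = float(min(1.0, ps.min() * len(ps))) if len(ps) > 1 else float(ps[0])
        return out

    def _factor_coef(self, names: list[str], values: np.ndarray) -> dict[str, float]:
        out: dict[str, float] = {}
        for factor in (HOST_FACTOR, STRAIN_FACTOR):
            idx = [i for i, nm in enumerate(names) if nm.startswith(f"{factor}[")]
            vals = values[idx]
            out[factor] = float(vals[np.argmax(np.abs(vals))])
        return out

    def _detect_separation(self, y: np.ndarray) -> bool:
        for factor in (HOST_FACTOR, STRAIN_FACTOR):
            tab = pd.crosstab(self.data[factor], y)
            if tab.shape[1] < 2 or (tab.to_numpy() == 0).any():
                return True
        return False

    def _fisher_fallback(self, y: np.ndarray, refs: dict[str, str]) -> FactorPartitionResult:
        params, bse, pvals = {}, {}, {}
        for factor in (HOST_FACTOR, STRAIN_FACTOR):
            levels = sorted(self.data[factor].astype(str).unique())
            # collapse to reference level vs pooled others
            is_ref = (self.data[factor].astype(str) == levels[0]).to_numpy()
            table = np.array(
                [
                    [int((y[is_ref] == 1).sum()), int((y[is_ref] == 0).sum())],
                    [int((y[~is_ref] == 1).sum()), int((y[~is_ref] == 0).sum())],
                ]
            )
            pvals[factor] = fisher_exact(table).p_value
            # Haldane-Anscombe corrected log odds ratio and Woolf SE
            t = table.astype(float) + 0.5
            params[factor] = float(
                math.log(t[1, 0] * t[0, 1] / (t[1, 1] * t[0, 0]))
            )
            bse[factor] = float(math.sqrt((1.0 / t).sum()))
        return FactorPartitionResult(
            params=params,
            bse=bse,
            p_values=pvals,
            model="fisher_fallback",
            separation=True,
            reference_levels=refs,
            nobs=len(self.data),
        )

    def fit(self) -> FactorPartitionResult:
        import statsmodels.api as sm

        X, names, refs = _design(self.data)
        if self.kind == "linear":
            y = self.data[self.response].to_numpy(float)
            res = sm.OLS(y, X).fit()
            coefs = np.asarray(res.params)[1:]
            ses = np.asarray(res.bse)[1:]
            ps = np.asarray(res.pvalues)[1:]
            sub = names[1:]
            return FactorPartitionResult(
                params=self._factor_coef(sub, coefs),
                bse=self._factor_coef(sub, ses),
                p_values=self._factor_pvals(sub, ps),
                model="linear",
                reference_levels=refs,
                nobs=len(self.data),
            )

        y = self.data[self.response].astype(bool).astype(int).to_numpy()
        if self._detect_separation(y):
            return self._fisher_fallback(y, refs)
        res = sm.Logit(y, X).fit(disp=0, maxiter=100)
        coefs = np.asarray(res.params)[1:]
        if np.any(np.abs(coefs) > 10):  # quasi-separation: diverging estimate
            return self._fisher_fallback(y, refs)
        sub = names[1:]
        return FactorPartitionResult(
            params=self._factor_coef(sub, coefs),
            bse=self._factor_coef(sub, np.asarray(res.bse)[1:]),
            p_values=self._factor_pvals(sub, np.asarray(res.pvalues)[1:]),
            model="logistic",
            reference_levels=refs,
            nobs=len(self.data),
        )


def partition_frequency(records: pd.DataFrame) -> FactorPartitionResult:
    """Logistic partition of per-hub tropism (boolean) into host and strain
    effects; falls back to Fisher exact tests under separation."""
    return FactorPartition.from_dataframe(records, response="tropism", kind="logistic").fit()


def partition_density(records: pd.DataFrame) -> FactorPartitionResult:
    """OLS partition of per-hub density ratios into host and strain effects."""
    return FactorPartition.from_dataframe(records, response="ratio", kind="linear").fit()


@dataclass
class GroupLettering:
    """Compact letter display: groups sharing any letter are not
    significantly different at the chosen alpha after Bonferroni."""

    letters: dict[str, str]
    pairwise: pd.DataFrame
    alpha: float = 0.05

    def __str__(self) -> str:
        return "\n".join(f"{g}: {l}" for g, l in self.letters.items())


def _compact_letters(
    groups: list[str], significant: set[tuple[str, str]]
) -> dict[str, str]:
    # Piepho-style insert-and-absorb on the significant pairs
    columns: list[set[str]] = [set(groups)]
    for a, b in significant:
        new_cols: list[set[str]] = []
        for col in columns:
            if a in col and b in col:
                new_cols.extend([col - {a}, col - {b}])
            else:
                new_cols.append(col)
        # absorb columns that are subsets of another
        columns = []
        for col in sorted(new_cols, key=len, reverse=True):
            if col and not any(col <= other for other in columns):
                columns.append(col)
    # deterministic letter order: by first member in group order
    order = {g: i for i, g in enumerate(groups)}
    columns.sort(key=lambda col: min(order[g] for g in col))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = {g: "" for g in groups}
    for i, col in enumerate(columns):
        letter = alphabet[i % len(alphabet)] * (1 + i // len(alphabet))
        for g in groups:
            if g in col:
                out[g] += letter
    return out


def assign_letters(
    groups: Mapping[str, tuple[int, int]] | Mapping[str, Sequence[float]],
    alpha: float = 0.05,
    test: str = "proportion",
    equal_var: bool = False,
) -> GroupLettering:
    """All-pairs comparison with Bonferroni correction and letter grouping.

    ``test="proportion"`` expects ``{label: (k, n)}`` counts and uses the
    pooled two-proportion z-test; ``test="t"`` expects ``{label: samples}``
    and uses pairwise t-tests (Welch by default).  Two groups receive a common
    letter iff their adjusted p is >= alpha.
    """
    if len(groups) < 2:
        raise ValueError("at least 2 groups are required")
    if test not in ("proportion", "t"):
        raise ValueError("test must be 'proportion' or 't'")
    labels = sorted(groups)
    if test == "proportion":
        for g, (k, n) in groups.items():
            if n == 0:
                raise ValueError(f"group {g!r} has n = 0")
    else:
        for g, samples in groups.items():
            if len(samples) == 0:
                raise ValueError(f"group {g!r} has no samples")

    pairs = list(itertools.combinations(labels, 2))
    m = len(pairs)
    rows = []
    significant: set[tuple[str, str]] = set()
    for a, b in pairs:
        if test == "proportion":
            ka, na = groups[a]
            kb, nb = groups[b]
            res = two_proportion_test(ka, na, kb, nb)
        else:
            stat, p = stats.ttest_ind(
                np.asarray(groups[a], float),
                np.asarray(groups[b], float),
                equal_var=equal_var,
            )
            res = TestResult(statistic=float(stat), p_value=float(p), method="t_test")
        p_adj = bonferroni(res.p_value, m)
        if p_adj < alpha:
            significant.add((a, b))
        rows.append(
            {
                "group1": a,
                "group2": b,
                "statistic": res.statistic,
                "p": res.p_value,
                "p_adj": p_adj,
                "significant": p_adj < alpha,
            }
        )
    letters = _compact_letters(labels, significant)
    return GroupLettering(letters=letters, pairwise=pd.DataFrame(rows), alpha=alpha)


def chi_square_groups(table: Sequence[Sequence[int]]) -> TestResult:
    """Pearson chi-square on a k x 2 count table (k-1 degrees of freedom)."""
    arr = np.asarray(table, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] != 2:
        raise ValueError("expect a k x 2 table with k >= 2")
    if np.any(arr < 0):
        raise ValueError("counts must be non-negative")
    row = arr.sum(axis=1, keepdims=True)
    col = arr.sum(axis=0, keepdims=True)
    expected = row @ col / arr.sum()
    if np.any(expected == 0):
        raise ValueError(
            "a zero expected count makes the chi-square approximation invalid; "
            "use fisher_exact on the informative 2x2 sub-tables instead"
        )
    stat, p, df, _ = stats.chi2_contingency(arr, correction=False)
    return TestResult(statistic=float(stat), p_value=float(p), df=float(df), method="chi_square")


def presence_correlation(
    paired_frequencies: Mapping[str, tuple[float, float]],
    method: str = "pearson",
) -> TestResult:
    """Correlation of paired (e.g. male vs female niche) tropism frequencies.

    Pearson by default with the two-sided t-based p; ``method="spearman"``
    switches to rank correlation.
    """
    if len(paired_frequencies) < 3:
        raise ValueError("at least 3 pairs are required")
    x = np.array([v[0] for v in paired_frequencies.values()], float)
    y = np.array([v[1] for v in paired_frequencies.values()], float)
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in one of the frequency vectors")
    if method == "pearson":
        r, p = stats.pearsonr(x, y)
    elif method == "spearman":
        r, p = stats.spearmanr(x, y)
    else:
        raise ValueError("method must be 'pearson' or 'spearman'")
    return TestResult(statistic=float(r), p_value=float(p), method=f"{method}_correlation")
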