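"""Case-control allele association and gene-burden statistics.

Each variant is a 2x2 allele table (case minor/major vs control
minor/major).  Two-sided Fisher exact p-values use the minimum-likelihood
definition (the one R's fisher.test implements), odds ratios are the
unconditional sample OR ad/bc (with optional Haldane 0.5 correction or an
infinity flag for zero cells), confidence intervals invert the noncentral
hypergeometric distribution (conditional exact), and multiple testing is
controlled by BH or Storey q-values.  The burden test is the same exact
test on carrier counts per group.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "AlleleTable",
    "allele_table_from_maf",
    "fisher_exact_two_sided",
    "odds_ratio",
    "conditional_mle_or",
    "exact_or_ci",
    "fdr_qvalues",
    "storey_pi0",
    "burden_test",
    "associate",
]


@dataclass(frozen=True)
class AlleleTable:
    """2x2 allele-count table; margins are 2n individuals per group."""

    a: int  # case minor alleles
    b: int  # case major alleles
    c: int  # control minor alleles
    d: int  # control major alleles

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if not float(v).is_integer() or v < 0:
                raise ValueError(f"cell {name} must be a nonnegative integer, got {v}")

    @property
    def n_cases(self) -> int:
        return (self.a + self.b) // 2

    @property
    def n_controls(self) -> int:
        return (self.c + self.d) // 2

    @property
    def maf_cases(self) -> float:
        tot = self.a + self.b
        return self.a / tot if tot else float("nan")

    @property
    def maf_controls(self) -> float:
        tot = self.c + self.d
        return self.c / tot if tot else float("nan")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=int)


def allele_table_from_maf(
    n_cases: int, n_controls: int, maf_cases: float, maf_controls: float
) -> AlleleTable:
    """Reconstruct allele counts from printed cohort sizes and MAFs.

    Minor counts are MAF * 2n rounded to the nearest integer with ties
    rounding up (floor(x + 0.5)); major counts are the complement.
    """

    def _round_half_up(x: float) -> int:
        return int(np.floor(x + 0.5))

    a = _round_half_up(maf_cases * 2 * n_cases)
    c = _round_half_up(maf_controls * 2 * n_controls)
    return AlleleTable(a=a, b=2 * n_cases - a, c=c, d=2 * n_controls - c)


def _as_table(table) -> AlleleTable:
    if isinstance(table, AlleleTable):
        return table
    arr = np.asarray(table, dtype=float)
    if not np.all(arr == np.floor(arr)):
        raise ValueError("table cells must be integers")
    return AlleleTable(int(arr[0, 0]), int(arr[0, 1]), int(arr[1, 0]), int(arr[1, 1]))


def fisher_exact_two_sided(table) -> float:
    """Two-sided Fisher exact p (minimum-likelihood definition).

    The p-value sums hypergeometric probabilities of all tables with the
    observed margins whose probability does not exceed the observed
    table's.
    """
    t = _as_table(table)
    return float(stats.fisher_exact(t.as_array(), alternative="two-sided")[1])


def odds_ratio(table, haldane_if_zero: bool = False) -> float:
    """Unconditional sample odds ratio ad / bc.

    With a zero cell: Haldane's correction (+0.5 to every cell) when the
    flag is set, else +inf (zero in b or c) / 0.0 (zero in a or d),
    matching how "Inf" rows are printed in association tables.
    """
    t = _as_table(table)
    a, b, c, d = float(t.a), float(t.b), float(t.c), float(t.d)
    if min(a, b, c, d) == 0:
        if haldane_if_zero:
            a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        else:
            if b == 0 or c == 0:
                return float("inf")
            return 0.0
    return a * d / (b * c)


def conditional_mle_or(table) -> float:
    """Conditional maximum-likelihood OR (what R's fisher.test reports)."""
    t = _as_table(table)
    res = stats.contingency.odds_ratio(t.as_array(), kind="conditional")
    return float(res.statistic)


def exact_or_ci(table, level: float = 0.95) -> tuple[float, float]:
    """Conditional exact confidence interval for the odds ratio.

    Inverts the Fisher noncentral hypergeometric tail: the lower bound is
    the psi with P(X >= a; psi) = alpha/2, the upper the psi with
    P(X <= a; psi) = alpha/2.  ``a`` at the support boundary gives 0 or
    +inf endpoints.
    """
    t = _as_table(table)
    a = t.a
    n1 = t.a + t.b  # case alleles drawn
    n2 = t.c + t.d
    m = t.a + t.c  # total minor alleles
    total = n1 + n2
    alpha = 1.0 - level
    lo_support = max(0, m - n2)
    hi_support = min(m, n1)

    def sf_at(psi: float) -> float:  # P(X >= a; psi)
        if a <= lo_support:
            return 1.0
        return float(stats.nchypergeom_fisher.sf(a - 1, total, n1, m, psi))

    def cdf_at(psi: float) -> float:  # P(X <= a; psi)
        if a >= hi_support:
            return 1.0
        return float(stats.nchypergeom_fisher.cdf(a, total, n1, m, psi))

    def solve(fun, target):
        # root of fun(exp(u)) - target over a wide log-odds grid
        g = lambda u: fun(np.exp(u)) - target
        lo, hi = -50.0, 50.0
        if g(lo) * g(hi) > 0:
            return np.exp(lo) if abs(g(lo)) < abs(g(hi)) else np.inf
        return float(np.exp(optimize.brentq(g, lo, hi, xtol=1e-10)))

    lower = 0.0 if a <= lo_support else solve(sf_at, alpha / 2.0)
    upper = float("inf") if a >= hi_support else solve(cdf_at, alpha / 2.0)
    return lower, upper


def storey_pi0(p: np.ndarray, lambdas: np.ndarray | None = None) -> float:
    """Storey's estimate of the null proportion pi0.

    pi0(lambda) = #{p > lambda} / (m (1 - lambda)) over the lambda grid
    0.05..0.95; a cubic smoother is evaluated at the largest lambda and
    the result clipped to (0, 1].
    """
    p = np.asarray(p, dtype=float)
    if lambdas is None:
        lambdas = np.arange(0.05, 0.96, 0.05)
    m = p.size
    pi0_l = np.array([(p > lam).sum() / (m * (1.0 - lam)) for lam in lambdas])
    if np.allclose(pi0_l, pi0_l[0]):
        pi0 = pi0_l[-1]
    else:
        coef = np.polyfit(lambdas, pi0_l, deg=3)
        pi0 = float(np.polyval(coef, lambdas[-1]))
    return float(min(max(pi0, 1.0 / m if m else 0.0), 1.0))


def fdr_qvalues(p: np.ndarray, method: str = "bh") -> np.ndarray:
    """FDR q-values: ``bh`` step-up, or ``storey`` = pi0 * BH."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if method == "bh":
        return multipletests(p, method="fdr_bh")[1]
    if method == "storey":
        pi0 = storey_pi0(p)
        return np.minimum(pi0 * multipletests(p, method="fdr_bh")[1], 1.0)
    raise ValueError(f"unknown FDR method {method!r}")


def burden_test(
    case_carriers: int, n_cases: int, ref_carriers: int, n_ref: int
) -> tuple[float, float]:
    """Carrier-count burden comparison between cohorts.

    Two-sided Fisher exact on carriers vs non-carriers per group; returns
    (p, OR) with OR = nan when undefined (no carriers anywhere).
    """
    if case_carriers > n_cases or ref_carriers > n_ref:
        raise ValueError("carriers cannot exceed cohort size")
    tab = np.array(
        [
            [case_carriers, n_cases - case_carriers],
            [ref_carriers, n_ref - ref_carriers],
        ]
    )
    p = float(stats.fisher_exact(tab, alternative="two-sided")[1])
    if case_carriers == 0 and ref_carriers == 0:
        return p, float("nan")
    t = AlleleTable(*tab.flatten().tolist())
    return p, odds_ratio(t)


def associate(
    variants: pd.DataFrame,
    fdr_method: str = "bh",
    ci_level: float = 0.95,
) -> pd.DataFrame:
    """Per-variant association results for a variant table.

    ``variants`` needs variant_id plus either raw counts (a, b, c, d) or
    (n_cases, n_controls, maf_cases, maf_controls).  Output mirrors a
    published association table: counts, MAFs, Fisher p, sample OR,
    conditional-MLE OR, exact CI and q-value.
    """
    rows = []
    for _, v in variants.iterrows():
        if {"a", "b", "c", "d"}.issubset(v.index) and not pd.isna(v.get("a")):
            t = AlleleTable(int(v["a"]), int(v["b"]), int(v["c"]), int(v["d"]))
        else:
            t = allele_table_from_maf(
                int(v["n_cases"]),
                int(v["n_controls"]),
                float(v["maf_cases"]),
                float(v["maf_controls"]),
            )
        p = fisher_exact_two_sided(t)
        lo, hi = exact_or_ci(t, level=ci_level)
        rows.append(
            {
                "variant_id": v["variant_id"],
                "a": t.a,
                "b": t.b,
                "c": t.c,
                "d": t.d,
                "n_cases": t.n_cases,
                "n_controls": t.n_controls,
                "maf_cases": t.maf_cases,
                "maf_controls": t.maf_controls,
                "fisher_p": p,
                "or_sample": odds_ratio(t),
                "or_cmle": conditional_mle_or(t),
                "ci_low": lo,
                "ci_high": hi,
            }
        )
    out = pd.DataFrame(rows)
    if len(out):
        out["q_value"] = fdr_qvalues(out["fisher_p"].to_numpy(), method=fdr_method)
    else:
        out["q_value"] = pd.Series(dtype=float)
    return out
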