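"""Between-library differential abundance: the Audic-Claverie (AC) tag-count
test, Benjamini-Hochberg FDR, fold changes, and the fraction-significant
summary.

The AC test asks whether observing count ``y`` of a feature in a library of
size ``N2`` is surprising given count ``x`` in a library of size ``N1``,
via the conditional distribution

    p(y | x) = (N2/N1)^y * (x+y)! / ( x! y! (1 + N2/N1)^(x+y+1) )

i.e. ``y | x`` is negative binomial with ``x+1`` successes and success
probability ``N1/(N1+N2)``.  The one-sided p-value is a tail mass of this
distribution, evaluated in log space with log-gamma so it is accurate for
counts far beyond floating-point factorials.

Tail convention.  Let L(y) = sum_{k<=y} p(k|x) (lower tail, inclusive).
If the observed rate y/N2 is below x/N1 the one-sided p is L(y); if above,
it is the complement 1 - L(y) (the strict upper tail); if the rates are
exactly equal the observation is the least extreme possible and p = 1.
This is the unique completion for which the test is exactly exchangeable,
p(x, y, N1, N2) = p(y, x, N2, N1): an inclusive tail on both sides would
double-count the boundary term p(y|x) under the swap.  The two-sided
p-value doubles the one-sided value and caps it at 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp
from statsmodels.stats.multitest import multipletests

from .functional import KOProfile

__all__ = ["ac_test", "bh_fdr", "compare_libraries", "ComparisonResult"]


def _ac_log_pmf(ks: np.ndarray, x: int, n1: float, n2: float) -> np.ndarray:
    log_r = np.log(n2) - np.log(n1)
    log_1pr = np.log1p(n2 / n1)
    return (
        ks * log_r
        + gammaln(x + ks + 1.0)
        - gammaln(x + 1.0)
        - gammaln(ks + 1.0)
        - (x + ks + 1.0) * log_1pr
    )


def _lower_tail(x: int, y: int, n1: float, n2: float) -> float:
    """sum_{k=0..y} p(k|x), via logsumexp."""
    ks = np.arange(0, y + 1, dtype=float)
    return float(np.exp(logsumexp(_ac_log_pmf(ks, x, n1, n2))))


def ac_test(x: int, y: int, n1: float, n2: float, sided: str = "two") -> float:
    """Audic-Claverie p-value for counts ``x`` (library size ``n1``) vs
    ``y`` (library size ``n2``).

    ``sided="one"`` returns the directional tail mass described in the
    module docstring; ``sided="two"`` (default) doubles it, capped at 1.
    """
    if n1 <= 0 or n2 <= 0:
        raise ValueError("library sizes must be positive")
    if x < 0 or y < 0:
        raise ValueError("counts must be non-negative")
    if sided not in ("one", "two"):
        raise ValueError(f"sided must be 'one' or 'two', got {sided!r}")

    rate_x = x / n1
    rate_y = y / n2
    if rate_y == rate_x:
        p_one = 1.0
    elif rate_y < rate_x:
        p_one = min(_lower_tail(x, y, n1, n2), 1.0)
    else:
        p_one = min(max(1.0 - _lower_tail(x, y, n1, n2), 0.0), 1.0)
    if sided == "one":
        return p_one
    return min(2.0 * p_one, 1.0)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in input order.

    Delegates to statsmodels' ``fdr_bh``; an independent step-up oracle
    lives in the test suite.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class ComparisonResult:
    """Feature-level AC comparison of two libraries."""

    results: pd.DataFrame   # feature, x, y, N1, N2, p_value, q_value, fold, significant
    significant_fraction: float
    alpha: float
    n_tested: int

    def significant_features(self) -> list[str]:
        return list(self.results.loc[self.results["significant"], "feature"])


def _integerize(weights: dict[str, float], mode: str) -> dict[str, int]:
    if mode == "round":
        # half-up, independent of banker's rounding
        return {k: int(np.floor(w + 0.5)) for k, w in weights.items()}
    if mode == "floor":
        return {k: int(np.floor(w)) for k, w in weights.items()}
    raise ValueError(f"unknown rounding mode {mode!r}")


def compare_libraries(
    profile_a: KOProfile,
    profile_b: KOProfile,
    alpha: float = 0.05,
    sided: str = "two",
    rounding: str = "round",
) -> ComparisonResult:
    """AC-test every KO present in either profile (absent = count 0).

    Counts entering the test are the tie-split weights rounded to integers
    (``rounding="round"`` half-up, or ``"floor"``); library sizes are the
    KEGG-assigned totals.  Features at zero in both libraries are skipped
    rather than tested at p = 1, which would only inflate the correction
    burden.  ``fold`` is percent_a / percent_b with an explicit ``inf``
    when the denominator percent is zero.
    """
    n1 = profile_a.n_kegg_assigned
    n2 = profile_b.n_kegg_assigned
    if n1 <= 0 or n2 <= 0:
        raise ValueError("both profiles must have KEGG-assigned reads")

    xa = _integerize(profile_a.weight, rounding)
    xb = _integerize(profile_b.weight, rounding)
    pa = profile_a.normalized
    pb = profile_b.normalized
    features = sorted(set(xa) | set(xb))

    rows = []
    for feat in features:
        x = xa.get(feat, 0)
        y = xb.get(feat, 0)
        if x == 0 and y == 0:
            continue
        p = ac_test(x, y, n1, n2, sided=sided)
        pct_a = pa.get(feat, 0.0)
        pct_b = pb.get(feat, 0.0)
        fold = np.inf if pct_b == 0.0 else pct_a / pct_b
        rows.append((feat, x, y, p, pct_a, pct_b, fold))

    if not rows:
        empty = pd.DataFrame(
            columns=["feature", "x", "y", "N1", "N2", "p_value", "q_value",
                     "percent_a", "percent_b", "fold", "significant"]
        )
        return ComparisonResult(empty, 0.0, alpha, 0)

    df = pd.DataFrame(
        rows, columns=["feature", "x", "y", "p_value", "percent_a", "percent_b", "fold"]
    )
    df.insert(3, "N1", n1)
    df.insert(4, "N2", n2)
    df["q_value"] = bh_fdr(df["p_value"].to_numpy())
    df["significant"] = df["q_value"] < alpha
    df = df[["feature", "x", "y", "N1", "N2", "p_value", "q_value",
             "percent_a", "percent_b", "fold", "significant"]]
    frac = float(df["significant"].mean())
    return ComparisonResult(df, frac, alpha, len(df))
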