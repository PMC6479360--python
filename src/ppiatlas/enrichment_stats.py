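"""Region enrichment statistics for variant distributions.

The probability of observing a variant in region *i* is x_i = n_i / N_i,
where n_i is the number of variant-bearing residues in the region and N_i
the region size.  Preferences between regions are expressed as odds ratios

    OR_ij = [x_i / (1 - x_i)] / [x_j / (1 - x_j)]

with a Woolf log-odds 95% confidence interval and a two-tailed Fisher exact
p-value on the corresponding 2x2 table.  Goodness of fit of observed counts
against a size-proportional random allocation uses the Pearson chi-squared
test, and per-type substitution susceptibility comparisons use the "N-1"
chi-squared variant (the Pearson statistic scaled by (N-1)/N), which keeps
its nominal size down to small expected counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

P_VALUE_FLOOR = 1e-12  # reporting floor; smaller values print as "<1e-12"


@dataclass
class RegionTally:
    """Residue totals and variant-bearing residue counts for one region."""
    region_name: str
    N_i: int
    n_i: int

    def __post_init__(self) -> None:
        if not (0 <= self.n_i <= self.N_i):
            raise ValueError(f"{self.region_name}: need 0 <= n_i <= N_i, "
                             f"got n_i={self.n_i}, N_i={self.N_i}")


@dataclass
class EnrichmentResult:
    region_i: str
    region_j: str
    x_i: float
    x_j: float
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    p_adjusted: float | None = None
    flags: list[str] = field(default_factory=list)


def variant_fraction(tally: RegionTally) -> float:
    """x_i = n_i / N_i, the per-residue variant probability of a region."""
    if tally.N_i == 0:
        raise ValueError(f"region {tally.region_name}: N_i = 0, fraction undefined")
    return tally.n_i / tally.N_i


def odds_ratio(tally_i: RegionTally, tally_j: RegionTally,
               alpha: float = 0.05) -> EnrichmentResult:
    """Odds ratio of carrying a variant in region i versus region j.

    Zero cells trigger the Haldane 0.5 continuity correction (flagged);
    a fraction of exactly 1 yields an infinite-odds flag.  The CI is the
    Woolf normal approximation on the log odds ratio.
    """
    x_i = variant_fraction(tally_i)
    x_j = variant_fraction(tally_j)
    a, b = tally_i.n_i, tally_i.N_i - tally_i.n_i
    c, d = tally_j.n_i, tally_j.N_i - tally_j.n_i
    flags: list[str] = []
    if x_i == 1.0 or x_j == 1.0 or x_i == 0.0 or x_j == 0.0:
        if x_i == 1.0 or x_j == 0.0:
            flags.append("infinite-odds")
        if x_j == 1.0 or x_i == 0.0:
            flags.append("zero-odds")
    if min(a, b, c, d) == 0:
        flags.append("haldane-corrected")
        ah, bh, ch, dh = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    else:
        ah, bh, ch, dh = a, b, c, d
    if "haldane-corrected" in flags:
        or_value = (ah / bh) / (ch / dh)
    else:
        or_value = (x_i / (1.0 - x_i)) / (x_j / (1.0 - x_j))
    z = stats.norm.ppf(1.0 - alpha / 2.0)
    se = float(np.sqrt(1 / ah + 1 / bh + 1 / ch + 1 / dh))
    log_or = float(np.log((ah / bh) / (ch / dh)))
    ci_low = float(np.exp(log_or - z * se))
    ci_high = float(np.exp(log_or + z * se))
    p = fisher_exact(a, b, c, d)
    return EnrichmentResult(region_i=tally_i.region_name, region_j=tally_j.region_name,
                            x_i=x_i, x_j=x_j, odds_ratio=or_value,
                            ci_low=ci_low, ci_high=ci_high, p_value=p, flags=flags)


def expected_counts(tallies: list[RegionTally]) -> list[tuple[str, float, float | None]]:
    """Expected variant-bearing residues per region under size-proportional
    random allocation, with the observed/expected ratio.

    expected_i = (sum of n) * N_i / (sum of N).
    """
    if len(tallies) < 2:
        raise ValueError("need at least two regions")
    total_n = sum(t.n_i for t in tallies)
    total_N = sum(t.N_i for t in tallies)
    if total_N == 0:
        raise ValueError("total residue count is zero")
    out = []
    for t in tallies:
        exp = total_n * t.N_i / total_N
        oe = t.n_i / exp if exp > 0 else None
        out.append((t.region_name, exp, oe))
    return out


def chi_square_gof(observed, expected) -> tuple[float, float]:
    """Pearson goodness-of-fit statistic and its two-tailed p (df = k - 1)."""
    observed = np.asarray(observed, dtype=float)
    expected = np.asarray(expected, dtype=float)
    if observed.shape != expected.shape:
        raise ValueError("observed and expected must have the same length")
    if np.any(expected <= 0):
        raise ValueError("expected counts must all be positive")
    statistic = float(((observed - expected) ** 2 / expected).sum())
    p = float(stats.chi2.sf(statistic, df=len(observed) - 1))
    return statistic, p


def fisher_exact(a: int, b: int, c: int, d: int) -> float:
    """Two-tailed Fisher exact p for the 2x2 table [[a, b], [c, d]]:
    the sum of hypergeometric probabilities of tables no more likely than
    the observed one."""
    for v in (a, b, c, d):
        if v < 0 or int(v) != v:
            raise ValueError("cells must be non-negative integers")
    if a + b + c + d == 0:
        raise ValueError("all-zero table")
    return float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])


def bonferroni(p_values, m: int) -> list[float]:
    """Bonferroni adjustment: min(1, p * m) for m planned comparisons."""
    p_values = list(p_values)
    if m < len(p_values):
        raise ValueError("m must be at least the number of p-values")
    return [min(1.0, p * m) for p in p_values]


def pearson_chi2_2x2(a: int, b: int, c: int, d: int) -> float:
    """Closed-form Pearson chi-squared statistic for a 2x2 table."""
    n = a + b + c + d
    r1, r2, c1, c2 = a + b, c + d, a + c, b + d
    denom = r1 * r2 * c1 * c2
    if denom == 0:
        return 0.0
    return n * (a * d - b * c) ** 2 / denom


def n_minus_one_chi_square(a: int, b: int, c: int, d: int) -> float:
    """Two-tailed p of the "N-1" chi-squared test on a 2x2 table:
    the Pearson statistic times (N-1)/N, referred to chi-squared with 1 df.

    Degenerate tables (a zero margin) return p = 1.
    """
    n = a + b + c + d
    if n < 2:
        raise ValueError("table total must be at least 2")
    if min(a + b, c + d, a + c, b + d) == 0:
        return 1.0
    statistic = pearson_chi2_2x2(a, b, c, d) * (n - 1) / n
    return float(stats.chi2.sf(statistic, df=1))


def format_p(p: float) -> str:
    """Report p-values with a floor: values below 1e-12 print as '<1e-12'."""
    if p < P_VALUE_FLOOR:
        return "<1e-12"
    return f"{p:.6g}"
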