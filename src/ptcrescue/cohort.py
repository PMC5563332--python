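"""Carrier-frequency summaries and stratified association statistics.

Implements the association toolkit used for carrier-burden analysis across
population strata: crude and Cochran-Mantel-Haenszel (CMH) summary odds
ratios with Robins-Breslow-Greenland confidence intervals, the exact
Hardy-Weinberg equilibrium test used for genotype QC (gate: p > 0.001),
pairwise linkage disequilibrium (EM haplotype frequencies, D' and r2), and
the Li-Ji spectral-decomposition effective number of tests for the
multiple-testing threshold.

Carrier-level (dominant) 2x2 tables are the unit of association.  Display
rounding is half-up to two decimals; all internal computation is full
precision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import chi2 as chi2_dist
from statsmodels.stats.contingency_tables import StratifiedTable

__all__ = [
    "StratumTable",
    "CMHResult",
    "GenotypeCounts",
    "LDResult",
    "UndefinedStatisticError",
    "carrier_stats",
    "crude_or",
    "cmh",
    "hwe_exact",
    "ld_pair",
    "meff_cutoff",
    "tabulate_cohort",
]


class UndefinedStatisticError(ValueError):
    pass


@dataclass(frozen=True)
class StratumTable:
    """Carrier/non-carrier counts for one population stratum.

    a: carrier patients, b: non-carrier patients,
    c: carrier controls, d: non-carrier controls.
    """

    stratum_label: str
    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cell counts must be >= 0")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("empty stratum table")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def has_empty_margin(self) -> bool:
        return (
            self.a + self.b == 0
            or self.c + self.d == 0
            or self.a + self.c == 0
            or self.b + self.d == 0
        )


@dataclass(frozen=True)
class CMHResult:
    or_mh: float
    ci_low: float
    ci_high: float
    chi2: float
    p: float
    n_strata_used: int
    n_strata_dropped: int = 0


@dataclass(frozen=True)
class GenotypeCounts:
    n_AA: int
    n_Aa: int
    n_aa: int

    def __post_init__(self) -> None:
        if min(self.n_AA, self.n_Aa, self.n_aa) < 0:
            raise ValueError("genotype counts must be >= 0")

    @property
    def total(self) -> int:
        return self.n_AA + self.n_Aa + self.n_aa


@dataclass(frozen=True)
class LDResult:
    r2: float
    d_prime: float
    haplotype_freqs: tuple[float, float, float, float]  # (AB, Ab, aB, ab)
    d: float
    em_iterations: int = 0


# ---------------------------------------------------------------------------
# Carrier summaries


def carrier_stats(n_carriers: int, n_total: int) -> tuple[float, float]:
    """(percentage rounded half-up to 2 decimals, exact fraction)."""
    if n_total <= 0:
        raise UndefinedStatisticError("n_total must be > 0")
    if not 0 <= n_carriers <= n_total:
        raise ValueError("need 0 <= n_carriers <= n_total")
    frac = n_carriers / n_total
    pct_rounded = float(
        (Decimal(100 * n_carriers) / Decimal(n_total)).quantize(
            Decimal("0.01"), rounding=ROUND_HALF_UP
        )
    )
    return pct_rounded, frac


# ---------------------------------------------------------------------------
# Odds ratios


@dataclass(frozen=True)
class CrudeOR:
    odds_ratio: float
    ci_low: float
    ci_high: float
    corrected: bool  # Haldane-Anscombe +0.5 applied


def crude_or(table: StratumTable, alpha: float = 0.05) -> CrudeOR:
    """Single-table odds ratio ad/bc with a Woolf (log-scale) 95% CI.

    When any cell is zero, 0.5 is added to all cells (Haldane-Anscombe) and
    the result is flagged ``corrected``.  Two zero cells in the same
    diagonal-product direction leave the OR undefined.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    corrected = 0 in (a, b, c, d)
    if table.has_empty_margin:
        raise UndefinedStatisticError("odds ratio undefined even after correction")
    if corrected:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    or_ = (a * d) / (b * c)
    z = float(abs(_z_for(alpha)))
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    lo = math.exp(math.log(or_) - z * se)
    hi = math.exp(math.log(or_) + z * se)
    return CrudeOR(or_, lo, hi, corrected)


def _z_for(alpha: float) -> float:
    from scipy.stats import norm

    return norm.ppf(1 - alpha / 2)


def cmh(strata: Sequence[StratumTable], alpha: float = 0.05) -> CMHResult:
    """Cochran-Mantel-Haenszel summary odds ratio across strata.

    OR_MH = sum(a_i d_i / n_i) / sum(b_i c_i / n_i); the 95% CI uses the
    Robins-Breslow-Greenland variance of log OR_MH; the CMH chi-square uses
    hypergeometric moments with no continuity correction.  Strata with an
    empty margin carry no information and are dropped (counted in
    ``n_strata_dropped``).
    """
    usable = [t for t in strata if not t.has_empty_margin]
    dropped = len(strata) - len(usable)
    if not usable:
        raise UndefinedStatisticError("all strata degenerate")
    tables = [np.array([[t.a, t.b], [t.c, t.d]], dtype=float) for t in usable]
    st = StratifiedTable(tables)
    or_mh = float(st.oddsratio_pooled)
    lo, hi = (float(x) for x in st.oddsratio_pooled_confint(alpha=alpha))
    test = st.test_null_odds(correction=False)
    return CMHResult(
        or_mh=or_mh,
        ci_low=lo,
        ci_high=hi,
        chi2=float(test.statistic),
        p=float(test.pvalue),
        n_strata_used=len(usable),
        n_strata_dropped=dropped,
    )


def tabulate_cohort(df: pd.DataFrame) -> list[StratumTable]:
    """Build per-stratum carrier tables from a per-individual cohort table.

    Expects columns ``cohort`` (patient/control), ``stratum``, ``carrier``
    (0/1).
    """
    tables = []
    for label, grp in df.groupby("stratum", sort=True):
        pat = grp[grp["cohort"] == "patient"]
        ctl = grp[grp["cohort"] == "control"]
        tables.append(
            StratumTable(
                str(label),
                a=int(pat["carrier"].sum()),
                b=int((1 - pat["carrier"]).sum()),
                c=int(ctl["carrier"].sum()),
                d=int((1 - ctl["carrier"]).sum()),
            )
        )
    return tables


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test


def hwe_exact(g: GenotypeCounts) -> float:
    """Exact Hardy-Weinberg equilibrium test by full enumeration.

    Conditional on the observed allele counts, sums the probabilities of all
    heterozygote counts no more probable than the observed one.  Monomorphic
    markers return p = 1.
    """
    n = g.total
    if n == 0:
        raise UndefinedStatisticError("no genotypes")
    n_a = 2 * g.n_AA + g.n_Aa  # copies of allele A
    n_b = 2 * g.n_aa + g.n_Aa
    if n_a == 0 or n_b == 0:
        return 1.0
    rare = min(n_a, n_b)
    # heterozygote count shares the parity of the rare-allele count
    h_values = [h for h in range(rare % 2, rare + 1, 2)]
    logps = []
    for h in h_values:
        n_hom_rare = (rare - h) // 2
        n_hom_common = (max(n_a, n_b) - h) // 2
        lp = (
            _logfact(n)
            - _logfact(n_hom_rare)
            - _logfact(h)
            - _logfact(n_hom_common)
            + h * math.log(2)
            + _logfact(n_a)
            + _logfact(n_b)
            - _logfact(2 * n)
        )
        logps.append(lp)
    logps = np.array(logps)
    probs = np.exp(logps - logps.max())
    probs /= probs.sum()
    obs = g.n_Aa
    p_obs = probs[h_values.index(obs)]
    return float(probs[probs <= p_obs * (1 + 1e-12)].sum())


def _logfact(n: int) -> float:
    return float(gammaln(n + 1))


# ---------------------------------------------------------------------------
# Linkage disequilibrium


def ld_pair(
    phased_counts: Optional[Sequence[int]] = None,
    genotype_table: Optional[np.ndarray] = None,
    tol: float = 1e-10,
    max_iter: int = 1000,
) -> LDResult:
    """Pairwise LD between two biallelic variants.

    Either ``phased_counts`` = (n_AB, n_Ab, n_aB, n_ab) haplotype counts, or
    ``genotype_table`` = a 3x3 array of unphased joint genotype counts
    (rows: AA/Aa/aa at the first variant, columns: BB/Bb/bb at the second),
    in which case haplotype frequencies are estimated by EM (converged when
    the largest frequency change is < ``tol``).

    Returns D = p_AB - p_A p_B, r2 = D^2 / (p_A p_a p_B p_b), and
    D' = |D| / D_max.
    """
    if (phased_counts is None) == (genotype_table is None):
        raise ValueError("provide exactly one of phased_counts or genotype_table")
    iterations = 0
    if phased_counts is not None:
        counts = np.asarray(phased_counts, dtype=float)
        if counts.shape != (4,) or counts.sum() <= 0:
            raise ValueError("phased_counts must be 4 non-negative counts")
        freqs = counts / counts.sum()
    else:
        freqs, iterations = _em_haplotypes(np.asarray(genotype_table, dtype=float),
                                           tol=tol, max_iter=max_iter)
    p_AB, p_Ab, p_aB, p_ab = (float(x) for x in freqs)
    p_A = p_AB + p_Ab
    p_B = p_AB + p_aB
    p_a = 1 - p_A
    p_b = 1 - p_B
    if min(p_A, p_a, p_B, p_b) <= 0:
        raise UndefinedStatisticError("monomorphic variant: LD undefined")
    d = p_AB - p_A * p_B
    r2 = d * d / (p_A * p_a * p_B * p_b)
    if d > 0:
        d_max = min(p_A * p_b, p_a * p_B)
    else:
        d_max = min(p_A * p_B, p_a * p_b)
    d_prime = abs(d) / d_max if d_max > 0 else 0.0
    return LDResult(
        r2=float(r2),
        d_prime=float(d_prime),
        haplotype_freqs=(p_AB, p_Ab, p_aB, p_ab),
        d=float(d),
        em_iterations=iterations,
    )


def _em_haplotypes(
    table: np.ndarray, tol: float, max_iter: int
) -> tuple[np.ndarray, int]:
    if table.shape != (3, 3) or table.min() < 0 or table.sum() <= 0:
        raise ValueError("genotype_table must be a non-negative 3x3 count array")
    n = table.sum()
    # haplotype counts contributed unambiguously; order (AB, Ab, aB, ab)
    base = np.zeros(4)
    # genotype (i alt copies at locus1? here i = index 0:AA,1:Aa,2:aa)
    contrib = {
        (0, 0): [(0, 2)],
        (0, 1): [(0, 1), (1, 1)],
        (0, 2): [(1, 2)],
        (1, 0): [(0, 1), (2, 1)],
        (1, 2): [(1, 1), (3, 1)],
        (2, 0): [(2, 2)],
        (2, 1): [(2, 1), (3, 1)],
        (2, 2): [(3, 2)],
    }
    for (i, j), haps in contrib.items():
        for h, k in haps:
            base[h] += k * table[i, j]
    dh = table[1, 1]  # double heterozygotes: AB/ab or Ab/aB
    freqs = np.full(4, 0.25)
    it = 0
    for it in range(1, max_iter + 1):
        cis = freqs[0] * freqs[3]
        trans = freqs[1] * freqs[2]
        denom = cis + trans
        x = 0.5 if denom == 0 else cis / denom
        counts = base.copy()
        counts[0] += dh * x
        counts[3] += dh * x
        counts[1] += dh * (1 - x)
        counts[2] += dh * (1 - x)
        new = counts / (2 * n)
        if np.max(np.abs(new - freqs)) < tol:
            freqs = new
            break
        freqs = new
    return freqs, it


# ---------------------------------------------------------------------------
# Effective number of tests


def meff_cutoff(
    correlation_matrix: np.ndarray, alpha: float = 0.05
) -> tuple[float, float]:
    """Li-Ji effective number of independent tests and p-value threshold.

    Uses the eigenvalues of the absolute-value correlation matrix:
    M_eff = sum_i [ I(lambda_i >= 1) + (lambda_i - floor(lambda_i)) ];
    threshold = alpha / M_eff.
    """
    corr = np.asarray(correlation_matrix, dtype=float)
    if corr.ndim != 2 or corr.shape[0] != corr.shape[1]:
        raise ValueError("correlation matrix must be square")
    if not np.allclose(corr, corr.T, atol=1e-8):
        raise ValueError("correlation matrix must be symmetric")
    eigvals = np.linalg.eigvalsh(np.abs(corr))
    m_eff = float(np.sum((eigvals >= 1).astype(float) + (eigvals - np.floor(eigvals))))
    return m_eff, alpha / m_eff
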