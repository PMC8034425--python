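"""Tumor-genomics statistics: alteration frequencies, co-occurrence
enrichment, expression group comparison, and survival analysis.

The co-occurrence analysis follows cBioPortal-style semantics: the cohort
is split by the alteration status of an index gene, and every other gene
gets a 2x2 comparison between the index-altered and index-unaltered groups
(group percentages, a log2 percentage ratio, a two-sided Fisher exact p,
and a Benjamini-Hochberg q across all tested genes). The log ratio is
computed from the group percentages, so published tables can be reproduced
without the unprinted group denominators.

Survival follows the usual nonparametric pipeline: median-split grouping,
Kaplan-Meier product-limit curves, the Mantel-Cox log-rank test, and the
observed/expected (Mantel-Haenszel) hazard ratio with a log-scale 95% CI.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

#: Sentinel log-ratio when one group's percentage is zero.
LOG_RATIO_INF = math.inf


@dataclass
class AlterationMatrix:
    """Binary sample x gene alteration calls with per-sample cancer types."""

    calls: pd.DataFrame          # index: sample ids, columns: gene symbols
    cancer_types: pd.Series      # index: sample ids

    def __post_init__(self) -> None:
        if not self.calls.index.equals(self.cancer_types.index):
            raise ValueError("calls and cancer_types must share sample index")
        values = self.calls.to_numpy()
        if not np.isin(values, (0, 1)).all():
            raise ValueError("alteration calls must be binary 0/1")

    @property
    def n_samples(self) -> int:
        return len(self.calls)


@dataclass
class SurvivalRecord:
    time: float   # months
    event: int    # 1 = death/progression, 0 = censored
    group: str = ""

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError("negative survival time")
        if self.event not in (0, 1):
            raise ValueError("event must be 0 or 1")


@dataclass
class KMCurve:
    """Kaplan-Meier step function: S(t) just after each event time."""

    times: np.ndarray      # distinct event times, ascending
    at_risk: np.ndarray    # number at risk just before each time
    survival: np.ndarray   # product-limit estimate after each time

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    def median_survival(self) -> float:
        below = np.nonzero(self.survival <= 0.5)[0]
        return float(self.times[below[0]]) if len(below) else math.inf


@dataclass
class LogrankResult:
    chi2: float
    p: float
    hr: float
    hr_ci: tuple[float, float]
    observed: tuple[float, float]   # (O_A, O_B)
    expected: tuple[float, float]   # (E_A, E_B)


# ---------------------------------------------------------------------------
# Alteration statistics

def alteration_frequency(
    matrix: AlterationMatrix, gene: str, by_cancer_type: bool = False
) -> dict:
    """Percent altered overall (rounded to integer) and optionally per type.

    The overall headline is rounded to the nearest integer percent
    (matching how cohort-level frequencies are reported); per-type
    percentages carry 2 decimals.
    """
    if gene not in matrix.calls.columns:
        raise KeyError(f"gene {gene!r} not in matrix")
    col = matrix.calls[gene]
    out = {
        "gene": gene,
        "altered": int(col.sum()),
        "total": int(len(col)),
        "pct": round(100.0 * col.sum() / len(col)),
    }
    if by_cancer_type:
        per_type = {}
        for ctype, sub in col.groupby(matrix.cancer_types):
            per_type[ctype] = round(100.0 * sub.sum() / len(sub), 2)
        out["by_cancer_type"] = per_type
    return out


def log2_pct_ratio(altered_pct: float, unaltered_pct: float) -> float:
    """log2 ratio of group percentages, 2 decimals; +/-inf on zero groups."""
    if altered_pct == 0 and unaltered_pct == 0:
        return 0.0
    if unaltered_pct == 0:
        return LOG_RATIO_INF
    if altered_pct == 0:
        return -LOG_RATIO_INF
    return round(math.log2(altered_pct / unaltered_pct), 2)


def fisher_exact(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the 2x2 table [[a, b], [c, d]].

    Two-sidedness by summation of hypergeometric point probabilities no
    larger than the observed table's. An all-zero table returns 1.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be non-negative")
    if a + b + c + d == 0:
        return 1.0
    return float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])


def bh_fdr(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values (monotone, q >= p)."""
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        return pvals
    if ((pvals < 0) | (pvals > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(pvals, method="fdr_bh")[1]


def cooccurrence_enrichment(
    matrix: AlterationMatrix, index_gene: str
) -> pd.DataFrame:
    """Per-gene co-occurrence statistics w.r.t. an index gene's status.

    One row per non-index gene: counts and percentages in the index-altered
    and index-unaltered groups, the log2 percentage ratio, two-sided Fisher
    p, BH q across all tested genes, and the enriched group. Genes with a
    zero percentage in either group carry a +/-inf log ratio and are
    flagged ``zero_group=True``.
    """
    if index_gene not in matrix.calls.columns:
        raise KeyError(f"index gene {index_gene!r} not in matrix")
    status = matrix.calls[index_gene] == 1
    n_alt, n_unalt = int(status.sum()), int((~status).sum())
    if n_alt == 0 or n_unalt == 0:
        raise ValueError("both index-altered and index-unaltered groups must be non-empty")

    rows = []
    for gene in matrix.calls.columns:
        if gene == index_gene:
            continue
        col = matrix.calls[gene]
        a = int(col[status].sum())            # altered in index-altered group
        c = int(col[~status].sum())           # altered in index-unaltered group
        alt_pct = 100.0 * a / n_alt
        unalt_pct = 100.0 * c / n_unalt
        lr = log2_pct_ratio(alt_pct, unalt_pct)
        rows.append(
            {
                "gene": gene,
                "altered_count": a,
                "altered_pct": round(alt_pct, 2),
                "unaltered_count": c,
                "unaltered_pct": round(unalt_pct, 2),
                "log_ratio": lr,
                "p": fisher_exact(a, n_alt - a, c, n_unalt - c),
                "enriched_in": "altered" if lr >= 0 else "unaltered",
                "zero_group": not math.isfinite(lr),
            }
        )
    df = pd.DataFrame(rows)
    if len(df):
        df["q"] = bh_fdr(df["p"].to_numpy())
        df = df.sort_values("p", kind="stable").reset_index(drop=True)
    return df


# ---------------------------------------------------------------------------
# Expression group comparison

def wilcoxon_ranksum(group_a, group_b) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test: (rank-sum statistic of A, p).

    Exact enumeration for small tie-free samples (nA + nB <= 12), normal
    approximation with midrank tie correction otherwise.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    has_ties = len(np.unique(np.concatenate([a, b]))) < a.size + b.size
    method = "exact" if (a.size + b.size <= 12 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    w = float(res.statistic + a.size * (a.size + 1) / 2.0)  # U -> rank sum
    return w, float(res.pvalue)


def median_split(expression: pd.Series) -> tuple[pd.Index, pd.Index]:
    """Split samples at the median: (high, low); median ties go low."""
    expression = expression.astype(float)
    if len(expression) < 2:
        raise ValueError("need at least 2 samples to split")
    med = float(expression.median())
    high = expression.index[expression > med]
    low = expression.index[expression <= med]
    if len(high) == 0:
        logger.warning("degenerate median split: no sample strictly above the median")
    return high, low


# ---------------------------------------------------------------------------
# Survival

def km_curve(records: list[SurvivalRecord]) -> KMCurve:
    """Product-limit survival estimator for one group."""
    if not records:
        raise ValueError("no survival records")
    times = np.array([r.time for r in records])
    events = np.array([r.event for r in records])
    event_times = np.unique(times[events == 1])
    at_risk, survival = [], []
    s = 1.0
    for t in event_times:
        n_risk = int((times >= t).sum())
        d = int(((times == t) & (events == 1)).sum())
        s *= 1.0 - d / n_risk
        at_risk.append(n_risk)
        survival.append(s)
    return KMCurve(
        times=event_times,
        at_risk=np.array(at_risk),
        survival=np.array(survival),
    )


def logrank_test(
    group_a: list[SurvivalRecord], group_b: list[SurvivalRecord]
) -> LogrankResult:
    """Mantel-Cox log-rank test with the O/E hazard ratio of A vs B.

    chi2 = (O_A - E_A)^2 / V on 1 df; HR = (O_A/E_A) / (O_B/E_B) with
    log-scale CI exp(log HR +/- 1.96 sqrt(1/E_A + 1/E_B)).
    """
    ta = np.array([r.time for r in group_a])
    ea = np.array([r.event for r in group_a])
    tb = np.array([r.time for r in group_b])
    eb = np.array([r.event for r in group_b])
    if ea.sum() == 0 and eb.sum() == 0:
        raise ValueError("log-rank test undefined: no events in either group")

    all_event_times = np.unique(np.concatenate([ta[ea == 1], tb[eb == 1]]))
    o_a = float(ea.sum())
    o_b = float(eb.sum())
    e_a = e_b = var = 0.0
    for t in all_event_times:
        n_a = float((ta >= t).sum())
        n_b = float((tb >= t).sum())
        n = n_a + n_b
        d = float(((ta == t) & (ea == 1)).sum() + ((tb == t) & (eb == 1)).sum())
        e_a += n_a * d / n
        e_b += n_b * d / n
        if n > 1:
            var += d * (n_a / n) * (n_b / n) * (n - d) / (n - 1)

    chi2 = (o_a - e_a) ** 2 / var if var > 0 else 0.0
    p = float(stats.chi2.sf(chi2, df=1))
    if o_a > 0 and o_b > 0 and e_a > 0 and e_b > 0:
        hr = (o_a / e_a) / (o_b / e_b)
        half = 1.96 * math.sqrt(1.0 / e_a + 1.0 / e_b)
        ci = (hr * math.exp(-half), hr * math.exp(half))
    else:
        hr, ci = math.nan, (math.nan, math.nan)
    return LogrankResult(
        chi2=chi2, p=p, hr=hr, hr_ci=ci,
        observed=(o_a, o_b), expected=(e_a, e_b),
    )


def read_survival_tsv(path) -> list[SurvivalRecord]:
    """Read survival records from TSV: sample_id, time_months, event, group."""
    df = pd.read_csv(path, sep="\t")
    return [
        SurvivalRecord(float(r.time_months), int(r.event), str(r.group))
        for r in df.itertuples()
    ]
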