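"""Serum-analyte screening: detectability filtering, log transform,
univariate group comparison, and subtype enrichment testing.

The screening stage mirrors standard multiplex-immunoassay practice:
analytes censored (below the LLOD) in more than 10% of samples are dropped;
the rest are analysed on the log10 scale with censored values imputed at
LLOD/2.  Group comparisons use two-sided Mann-Whitney U tests with
Benjamini-Hochberg FDR control and pooled-SD Cohen's d.  The enrichment
test asks whether as many analytes would be elevated in a random patient
subset of the same size as in a given subtype, using repeated random
drawings; the combined-sample ranks are fixed across drawings, so the null
is computed exactly as a rank-sum over random subsets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .analytes import AnalytePanel


def llod_filter(panel: AnalytePanel, max_censored_fraction: float = 0.10) -> list[str]:
    """Analytes retained by the detectability screen.

    An analyte is excluded when strictly more than `max_censored_fraction`
    of the samples fall below its LLOD; a censored fraction exactly at the
    threshold is retained.
    """
    frac = panel.censored_fraction()
    keep = frac <= max_censored_fraction + 1e-12
    return [a for a in panel.analyte_names if keep[a]]


def log_transform(panel: AnalytePanel, retained: list[str] | None = None) -> pd.DataFrame:
    """log10 concentrations for the retained analytes.

    Censored entries are imputed at LLOD/2 before the transform.  An
    uncensored non-positive concentration is a data error.
    """
    retained = panel.analyte_names if retained is None else list(retained)
    conc = panel.concentrations[retained].to_numpy(dtype=float).copy()
    mask = panel.below_llod[retained].to_numpy(dtype=bool)
    llod = panel.llod.loc[retained].to_numpy(dtype=float)
    bad = (conc <= 0) & ~mask
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"non-positive uncensored concentration for analyte {retained[j]!r} "
            f"(patient {panel.patient_ids[i]!r})"
        )
    conc[mask] = np.broadcast_to(llod / 2.0, conc.shape)[mask]
    return pd.DataFrame(np.log10(conc), index=panel.patient_ids, columns=retained)


# ---------------------------------------------------------------------------
# Univariate comparison
# ---------------------------------------------------------------------------


@dataclass
class UnivariateResult:
    """Per-analyte two-group comparison: means, U, p, BH-FDR q, Cohen's d."""

    table: pd.DataFrame
    q_threshold: float = 0.1

    @property
    def significant(self) -> pd.Index:
        return self.table.index[self.table["q"] < self.q_threshold]

    def significant_higher(self) -> pd.Index:
        """Analytes significant at the FDR threshold AND higher in group 1."""
        t = self.table
        return t.index[(t["q"] < self.q_threshold) & (t["direction"] > 0)]


def cohens_d(x1: np.ndarray, x2: np.ndarray) -> float:
    """Standardized mean difference with pooled SD."""
    n1, n2 = len(x1), len(x2)
    v1 = x1.var(ddof=1) if n1 > 1 else 0.0
    v2 = x2.var(ddof=1) if n2 > 1 else 0.0
    denom_df = n1 + n2 - 2
    if denom_df <= 0:
        return np.nan
    pooled = np.sqrt(((n1 - 1) * v1 + (n2 - 1) * v2) / denom_df)
    if pooled == 0:
        return 0.0 if x1.mean() == x2.mean() else np.inf * np.sign(x1.mean() - x2.mean())
    return float((x1.mean() - x2.mean()) / pooled)


def univariate_compare(
    log_table: pd.DataFrame,
    grouping,
    q_threshold: float = 0.1,
    method: str = "auto",
) -> UnivariateResult:
    """Two-sided Mann-Whitney comparison of every analyte between two groups.

    `grouping` is a boolean vector (True = group 1); p-values are BH
    step-up adjusted across the analytes of the table.
    """
    g = np.asarray(grouping, dtype=bool)
    if g.shape[0] != log_table.shape[0]:
        raise ValueError("grouping length does not match table")
    if g.all() or not g.any():
        raise ValueError("both groups must be nonempty")
    x1 = log_table.to_numpy(dtype=float)[g]
    x2 = log_table.to_numpy(dtype=float)[~g]
    res = stats.mannwhitneyu(x1, x2, axis=0, alternative="two-sided", method=method)
    u = np.atleast_1d(res.statistic).astype(float)
    p = np.atleast_1d(res.pvalue).astype(float)
    q = multipletests(p, method="fdr_bh")[1]
    rows = []
    for j, a in enumerate(log_table.columns):
        d = cohens_d(x1[:, j], x2[:, j])
        rows.append(
            {
                "mean_group1": x1[:, j].mean(),
                "mean_group2": x2[:, j].mean(),
                "U": u[j],
                "p": p[j],
                "q": q[j],
                "cohens_d": d,
                "direction": int(np.sign(x1[:, j].mean() - x2[:, j].mean())),
            }
        )
    table = pd.DataFrame(rows, index=log_table.columns)
    return UnivariateResult(table=table, q_threshold=q_threshold)


# ---------------------------------------------------------------------------
# Enrichment test
# ---------------------------------------------------------------------------


@dataclass
class EnrichmentResult:
    """Random-drawing enrichment of elevated analytes in a subtype."""

    observed_count: int
    n_drawings: int
    null_counts: np.ndarray = field(repr=False)
    p_empirical: float
    p_parametric: float
    q_threshold: float


def _ranksum_pq(
    ranks: np.ndarray, tie_term: np.ndarray, subset: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized two-sided normal-approximation Mann-Whitney p for one or
    many subsets, from precomputed combined-sample ranks.

    `ranks`: m x p matrix of per-analyte midranks; `tie_term`: per-analyte
    sum of (t^3 - t) over tie groups; `subset`: boolean m-vector or m x B
    matrix of group-1 memberships.  Returns (U1, p) with continuity
    correction, matching the asymptotic Mann-Whitney convention.
    """
    m = ranks.shape[0]
    sub = subset.astype(float)
    if sub.ndim == 1:
        sub = sub[:, None]
    n1 = sub.sum(axis=0)  # B
    n2 = m - n1
    r1 = np.einsum("mp,mb->bp", ranks, sub)
    u1 = r1 - n1[:, None] * (n1[:, None] + 1) / 2.0
    mu = (n1 * n2 / 2.0)[:, None]
    sigma2 = (n1 * n2 / 12.0)[:, None] * ((m + 1) - tie_term[None, :] / (m * (m - 1)))
    sigma = np.sqrt(np.maximum(sigma2, 0.0))
    num = np.abs(u1 - mu) - 0.5  # continuity correction
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(sigma > 0, np.maximum(num, 0.0) / sigma, 0.0)
    p = np.minimum(2.0 * stats.norm.sf(z), 1.0)
    return u1, p


def _bh_adjust_rows(p: np.ndarray) -> np.ndarray:
    """Vectorized Benjamini-Hochberg step-up over the last axis."""
    B, k = p.shape
    order = np.argsort(p, axis=1)
    ranked = np.take_along_axis(p, order, axis=1)
    scaled = ranked * k / np.arange(1, k + 1)[None, :]
    q_sorted = np.minimum.accumulate(scaled[:, ::-1], axis=1)[:, ::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty_like(q_sorted)
    np.put_along_axis(q, order, q_sorted, axis=1)
    return q


def subtype_enrichment(
    log_table: pd.DataFrame,
    subtype_mask,
    n_drawings: int = 10_000,
    q_threshold: float = 0.1,
    seed: int | None = None,
) -> EnrichmentResult:
    """How surprising is the subtype's count of significantly elevated analytes?

    The observed count is the number of analytes with BH-FDR q below the
    threshold AND a higher mean in the subtype.  The null distribution
    recomputes that count for uniformly random patient subsets of the same
    size.  Reports the empirical tail probability with the +1 pseudocount
    and a Poisson-tail parametric estimate fitted to the null counts (an
    empirical estimate is floored at 1/(n_drawings+1), so very extreme
    enrichments are better summarised parametrically).
    """
    mask = np.asarray(subtype_mask, dtype=bool)
    if mask.shape[0] != log_table.shape[0]:
        raise ValueError("subtype mask length does not match table")
    if not mask.any() or mask.all():
        raise ValueError("subtype must be a nonempty proper subset of the patients")
    if n_drawings < 1:
        raise ValueError("n_drawings must be >= 1")
    m, k = log_table.shape
    vals = log_table.to_numpy(dtype=float)
    ranks = stats.rankdata(vals, axis=0)
    tie_term = np.empty(k)
    for j in range(k):
        _, counts = np.unique(vals[:, j], return_counts=True)
        tie_term[j] = float((counts**3 - counts).sum())

    def elevated_count(subsets: np.ndarray) -> np.ndarray:
        _, p = _ranksum_pq(ranks, tie_term, subsets)
        q = _bh_adjust_rows(p)
        sub = subsets.astype(float)
        if sub.ndim == 1:
            sub = sub[:, None]
        n1 = sub.sum(axis=0)
        mean1 = (vals.T @ sub).T / n1[:, None]
        mean2 = (vals.sum(axis=0)[None, :] - mean1 * n1[:, None]) / (m - n1)[:, None]
        return ((q < q_threshold) & (mean1 > mean2)).sum(axis=1)

    observed = int(elevated_count(mask)[0])
    n_sub = int(mask.sum())
    rng = np.random.default_rng(seed)
    null_counts = np.empty(n_drawings, dtype=int)
    batch = 200
    done = 0
    while done < n_drawings:
        b = min(batch, n_drawings - done)
        subsets = np.zeros((m, b), dtype=bool)
        for col in range(b):
            subsets[rng.choice(m, size=n_sub, replace=False), col] = True
        null_counts[done : done + b] = elevated_count(subsets)
        done += b
    p_emp = (1 + int((null_counts >= observed).sum())) / (n_drawings + 1)
    lam = float(null_counts.mean())
    p_par = float(stats.poisson.sf(observed - 1, lam)) if observed > 0 else 1.0
    return EnrichmentResult(
        observed_count=observed,
        n_drawings=n_drawings,
        null_counts=null_counts,
        p_empirical=float(p_emp),
        p_parametric=p_par,
        q_threshold=q_threshold,
    )
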