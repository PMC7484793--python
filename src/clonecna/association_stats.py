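"""Association statistics used by the pipeline.

* :func:`wilcoxon_rank_test` — Wilcoxon rank-sum / Mann–Whitney test,
  reporting the U statistic of the first group (the convention under which
  values like ``W = 17,081`` are printed).  The p-value is exact (full
  enumeration of rank assignments) when the pooled sample is small
  (``n1 + n2 <= exact_limit``, default 12) and tie-free; otherwise a
  normal approximation with tie-corrected variance and a signed 0.5
  continuity correction is used, reproducing the convention of R's
  ``wilcox.test`` (in particular p = 1 exactly when U sits at its null
  mean in a two-sided test).
* :func:`chi_squared_test` — Pearson chi-squared for r × c contingency
  tables; the Yates continuity correction is applied only to 2 × 2 tables,
  where it is defined, even when requested for larger tables.
* :func:`fisher_exact_two_sided` — two-sided Fisher exact p for 2 × 2
  tables: the sum of hypergeometric probabilities of all tables with the
  observed margins whose probability does not exceed the observed one.
* :func:`cna_expression_screen` — per-gene one-sided rank test of
  expression (TPM) in gained vs non-gained samples, with
  Benjamini–Hochberg correction across the screened set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cna_calling import GAIN_STATES, STATE_MISSING
from .errors import ValidationError

__all__ = [
    "RankTestResult",
    "ChiSquareResult",
    "wilcoxon_rank_test",
    "chi_squared_test",
    "fisher_exact_two_sided",
    "bh_adjust",
    "cna_expression_screen",
]

ALTERNATIVES = ("greater", "two_sided")


@dataclass(frozen=True)
class RankTestResult:
    statistic: float  # Mann–Whitney U of the first group
    p_value: float
    n1: int
    n2: int
    alternative: str
    method: str  # "exact" | "normal_approx"


@dataclass(frozen=True)
class ChiSquareResult:
    chi2: float
    df: int
    p_value: float
    continuity_corrected: bool


def wilcoxon_rank_test(group1, group2, alternative: str = "greater", exact_limit: int = 12) -> RankTestResult:
    """Rank-sum test that group1 is stochastically larger (or differs, two-sided)."""
    x = np.asarray(group1, dtype=float)
    y = np.asarray(group2, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("wilcoxon_rank_test: both groups must be non-empty")
    if alternative not in ALTERNATIVES:
        raise ValidationError(f"wilcoxon_rank_test: alternative must be one of {ALTERNATIVES}")
    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    ranks = stats.rankdata(pooled)
    u1 = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2)

    if n1 + n2 <= exact_limit and not has_ties:
        alt = "two-sided" if alternative == "two_sided" else "greater"
        res = stats.mannwhitneyu(x, y, alternative=alt, method="exact")
        return RankTestResult(float(res.statistic), float(res.pvalue), n1, n2, alternative, "exact")

    # normal approximation, tie-corrected sigma, signed 0.5 continuity correction
    n = n1 + n2
    mean = n1 * n2 / 2
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    sigma2 = (n1 * n2 / 12) * ((n + 1) - tie_term / (n * (n - 1)))
    z = u1 - mean
    if sigma2 <= 0:  # all observations tied
        p = 1.0
    else:
        if alternative == "greater":
            z = (z - 0.5) / math.sqrt(sigma2)
            p = stats.norm.sf(z)
        else:
            correction = 0.5 * np.sign(z)
            zc = (z - correction) / math.sqrt(sigma2)
            p = 2 * min(stats.norm.cdf(zc), stats.norm.sf(zc))
        p = float(min(1.0, p))
    return RankTestResult(u1, p, n1, n2, alternative, "normal_approx")


def _as_int_table(table) -> np.ndarray:
    t = np.asarray(table)
    if t.ndim != 2:
        raise ValidationError("contingency table must be 2-dimensional")
    if not np.all(np.equal(np.mod(t, 1), 0)):
        raise ValidationError("contingency table cells must be integers")
    t = t.astype(np.int64)
    if (t < 0).any():
        raise ValidationError("contingency table cells must be non-negative")
    return t


def chi_squared_test(table, continuity: bool = True) -> ChiSquareResult:
    """Pearson chi-squared test of independence for an r × c count table.

    The Yates correction is applied only when the table is 2 × 2 (df = 1),
    regardless of ``continuity`` — the correction is undefined for larger
    tables.
    """
    t = _as_int_table(table)
    if t.shape[0] < 2 or t.shape[1] < 2:
        raise ValidationError("chi_squared_test: need at least 2 rows and 2 columns")
    if (t.sum(axis=1) == 0).any() or (t.sum(axis=0) == 0).any():
        raise ValidationError("chi_squared_test: zero marginal row or column")
    res = stats.chi2_contingency(t, correction=continuity)
    corrected = bool(continuity and t.shape == (2, 2))
    return ChiSquareResult(float(res.statistic), int(res.dof), float(res.pvalue), corrected)


def fisher_exact_two_sided(table) -> float:
    """Two-sided Fisher exact p-value for a 2 × 2 table (1.0 on a zero margin)."""
    t = _as_int_table(table)
    if t.shape != (2, 2):
        raise ValidationError("fisher_exact_two_sided: table must be 2x2")
    return float(stats.fisher_exact(t, alternative="two-sided")[1])


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg adjusted q-values (monotone in p-value rank)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    return stats.false_discovery_control(p, method="bh")


def cna_expression_screen(
    gene_calls: pd.DataFrame,
    expression: pd.DataFrame,
    genes=None,
    q_threshold: float = 0.05,
) -> pd.DataFrame:
    """Screen genes for higher expression in gained vs non-gained samples.

    ``gene_calls`` holds one row per sample × gene with a ``state`` column
    (regions are the samples in multi-region data; one region per tumour in
    per-sample data); ``expression`` is the sample × gene TPM matrix.  A
    sample enters a gene's test only when both its call (non-missing) and
    its TPM value are present.  Genes without at least one gained and one
    non-gained sample are reported with ``tested = False``.

    Returns one row per gene: ``gene, n_gain, n_nogain, W, p, q, tested,
    significant`` with BH correction across the tested genes and the
    "significantly gained and expressed" flag at ``q < q_threshold``.
    """
    sample_col = "region_id" if "region_id" in gene_calls.columns else "sample"
    if genes is None:
        genes = sorted(set(gene_calls["gene"]) & set(expression.columns))
    rows = []
    for gene in genes:
        calls = gene_calls[gene_calls["gene"] == gene]
        row = {"gene": gene, "n_gain": 0, "n_nogain": 0, "W": np.nan, "p": np.nan,
               "tested": False}
        if gene not in expression.columns or calls.empty:
            rows.append(row)
            continue
        expr = expression[gene]
        merged = calls[[sample_col, "state"]].copy()
        merged["tpm"] = expr.reindex(merged[sample_col].astype(str)).to_numpy()
        merged = merged[(merged["state"] != STATE_MISSING) & merged["tpm"].notna()]
        gained = merged.loc[merged["state"].isin(GAIN_STATES), "tpm"].to_numpy()
        not_gained = merged.loc[~merged["state"].isin(GAIN_STATES), "tpm"].to_numpy()
        row["n_gain"], row["n_nogain"] = gained.size, not_gained.size
        if gained.size and not_gained.size:
            res = wilcoxon_rank_test(gained, not_gained, alternative="greater")
            row.update(W=res.statistic, p=res.p_value, tested=True)
        rows.append(row)
    out = pd.DataFrame(rows)
    out["q"] = np.nan
    tested = out["tested"].to_numpy()
    if tested.any():
        out.loc[tested, "q"] = bh_adjust(out.loc[tested, "p"].to_numpy())
    out["significant"] = out["q"] < q_threshold
    return out
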