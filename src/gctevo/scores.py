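"""Expression/methylation scores and the cohort statistics layer.

* Replication-stress score: per-gene z-scores across samples are weighted
  by a signed 17-gene signature, summed per sample, and the sums are
  z-normalized again across samples (population standard deviation).
* Methylation summaries: probes are filtered by raw median absolute
  deviation (MAD > 0.1, unscaled) across samples, then the per-sample
  median beta is reported for chromosome X and autosomal probes.
* Association tests: two-sided Wilcoxon rank-sum (exact for small
  samples), two-sided Fisher's exact with the conditional-MLE odds ratio,
  covariate-adjusted ordinary least squares, and Benjamini-Hochberg FDR.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .genome import AUTOSOMES


@dataclass
class AssocResult:
    test: str                 # wilcoxon | fisher | linear
    statistic: float
    p_value: float
    effect: float             # difference / odds ratio / coefficient
    effect_name: str
    extra: dict | None = None


# ---------------------------------------------------------------------------
# replication-stress score
# ---------------------------------------------------------------------------

def replication_stress_score(expr: pd.DataFrame, weights: pd.Series,
                             zscore_axis: str = "genes") -> pd.Series:
    """Weighted z-score signature of replication-stress genes.

    Parameters
    ----------
    expr
        Expression matrix, genes x samples.
    weights
        Signed gene weights; genes missing from ``expr`` are dropped with
        a warning.  All-zero weights are an error.
    zscore_axis
        "genes" (default): z-score each gene across samples before
        weighting.  "samples": z-score each sample across genes instead.
    """
    import warnings

    if expr.shape[1] < 2:
        raise ValueError("need >= 2 samples")
    present = weights.index.intersection(expr.index)
    missing = weights.index.difference(expr.index)
    if len(missing):
        warnings.warn(f"{len(missing)} weighted genes absent from matrix; dropped")
    w = weights.loc[present]
    if len(w) == 0 or (w == 0).all():
        raise ValueError("no nonzero gene weights usable")

    sub = expr.loc[present].astype(float)
    if zscore_axis == "genes":
        mu = sub.mean(axis=1)
        sd = sub.std(axis=1, ddof=0)
    elif zscore_axis == "samples":
        mu = sub.mean(axis=0)
        sd = sub.std(axis=0, ddof=0)
    else:
        raise ValueError("zscore_axis must be 'genes' or 'samples'")
    axis = 0 if zscore_axis == "genes" else 1
    zero_var = sd == 0
    if zero_var.any():
        warnings.warn(f"{int(zero_var.sum())} zero-variance entries; z set to 0")
    sd = sd.replace(0, np.inf)
    z = sub.sub(mu, axis=axis).div(sd, axis=axis)

    raw = z.mul(w, axis=0).sum(axis=0)
    sd_raw = raw.std(ddof=0)
    if sd_raw == 0:
        return raw * 0.0
    return (raw - raw.mean()) / sd_raw


# ---------------------------------------------------------------------------
# methylation
# ---------------------------------------------------------------------------

def methylation_summary(beta: pd.DataFrame, probe_map: pd.DataFrame,
                        mad_threshold: float = 0.1) -> pd.DataFrame:
    """Per-sample median beta for chromosome X and autosomal probes.

    Probes with raw (unscaled) MAD <= ``mad_threshold`` across samples are
    dropped first; an empty surviving set is an error.
    """
    med = beta.median(axis=1)
    mad = (beta.sub(med, axis=0)).abs().median(axis=1)
    kept = beta[mad > mad_threshold]
    if kept.empty:
        raise ValueError(f"no probes with MAD > {mad_threshold}")
    chrom = probe_map.set_index("probe")["chrom"]
    on_x = kept.index[chrom.reindex(kept.index) == "X"]
    on_auto = kept.index[chrom.reindex(kept.index).isin(AUTOSOMES)]
    return pd.DataFrame({
        "median_beta_x": kept.loc[on_x].median(axis=0) if len(on_x) else np.nan,
        "median_beta_auto": kept.loc[on_auto].median(axis=0) if len(on_auto) else np.nan,
    })


# ---------------------------------------------------------------------------
# association tests
# ---------------------------------------------------------------------------

def wilcoxon_rank_sum(x, y, exact_max_n: int = 25) -> AssocResult:
    """Two-sided Mann-Whitney U; exact null for small tie-free samples,
    otherwise normal approximation with tie correction."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs >= 2 observations")
    has_ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    method = "exact" if (max(len(x), len(y)) <= exact_max_n and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return AssocResult("wilcoxon", float(res.statistic), float(res.pvalue),
                       float(np.median(x) - np.median(y)), "median_difference")


def _conditional_mle_or(table: np.ndarray) -> float:
    """Conditional maximum-likelihood odds ratio of a 2x2 table.

    Maximizes the Fisher noncentral hypergeometric likelihood of the
    observed first cell given the margins (the estimator reported by
    standard exact-test implementations).
    """
    a, b = table[0]
    c, d = table[1]
    n1, n2, m1 = a + b, c + d, a + c
    lo = max(0, m1 - n2)
    hi = min(m1, n1)
    if a == lo:
        return 0.0
    if a == hi:
        return np.inf

    def neg_loglik(log_or: float) -> float:
        return -stats.nchypergeom_fisher.logpmf(a, n1 + n2, n1, m1, np.exp(log_or))

    res = optimize.minimize_scalar(neg_loglik, bounds=(-50, 50), method="bounded",
                                   options={"xatol": 1e-10})
    return float(np.exp(res.x))


def fisher_exact_test(table) -> AssocResult:
    """Two-sided Fisher's exact test with conditional-MLE odds ratio.

    The sample (cross-product) odds ratio is reported alongside in
    ``extra``.
    """
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2):
        raise ValueError("need a 2x2 table")
    sample_or, p = stats.fisher_exact(t, alternative="two-sided")
    cmle = _conditional_mle_or(t)
    return AssocResult("fisher", float(sample_or), float(p), float(cmle),
                       "odds_ratio_cmle", extra={"odds_ratio_sample": float(sample_or)})


def linear_association(table: pd.DataFrame, response: str, predictor: str,
                       covariates: list[str] | None = None) -> AssocResult:
    """OLS of ``response`` on ``predictor`` adjusting for covariates."""
    import statsmodels.api as sm

    covariates = covariates or []
    cols = [predictor] + covariates
    clean = table[[response] + cols].dropna()
    if len(clean) < len(cols) + 2:
        raise ValueError("too few complete observations for regression")
    y = clean[response].astype(float)
    X = sm.add_constant(clean[cols].astype(float))
    if y.nunique() == 1:
        return AssocResult("linear", 0.0, 1.0, 0.0, f"beta[{predictor}]")
    fit = sm.OLS(y, X).fit()
    return AssocResult("linear", float(fit.tvalues[predictor]),
                       float(fit.pvalues[predictor]),
                       float(fit.params[predictor]), f"beta[{predictor}]")


def association_tests(table: pd.DataFrame | np.ndarray, spec: dict) -> AssocResult:
    """Dispatch on ``spec['test']`` in {wilcoxon, fisher, linear}.

    wilcoxon: spec names ``response`` and binary ``group`` columns.
    fisher: ``table`` is the 2x2 array.  linear: spec names ``response``,
    ``predictor`` and optional ``covariates``.
    """
    test = spec["test"]
    if test == "wilcoxon":
        groups = table.groupby(spec["group"])[spec["response"]]
        vals = [g.to_numpy() for _, g in groups]
        if len(vals) != 2:
            raise ValueError("wilcoxon requires exactly 2 groups")
        return wilcoxon_rank_sum(vals[0], vals[1])
    if test == "fisher":
        return fisher_exact_test(table)
    if test == "linear":
        return linear_association(table, spec["response"], spec["predictor"],
                                  spec.get("covariates"))
    raise ValueError(f"unknown test {test!r}")


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, input order preserved.

    q_i = min over j with p_(j) >= p_(i) of p_(j) * m / rank(j), clipped
    at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([])
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q
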