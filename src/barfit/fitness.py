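"""Fitness contrasts between growth stages from barcode counts.

The count model is the standard negative-binomial one for sequencing
counts: Var(K) = μ + α μ², with per-sample depth absorbed by
median-of-ratios size factors.  Each strain is tested for a change in
relative abundance between two stages (e.g. pool → batch, or early → late
steady state) with a Wald test on the log2 ratio of group means, the
standard error coming from the delta method under the NB variance.  A
strain is called haplo-proficient (HP) when it is significantly
over-represented by at least the fold threshold, haplo-insufficient (HI)
when under-represented.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from barfit.errors import ParameterError, ValidationError

LN2 = np.log(2.0)

RESULT_COLUMNS = ["baseMean", "log2fc", "se", "p", "padj", "call"]


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors.

    sf_j = median over strains (positive in every sample) of
    count_ij / geometric-mean_i.
    """
    mat = counts.to_numpy(dtype=float)
    positive = (mat > 0).all(axis=1)
    if not positive.any():
        raise ValidationError(
            "no strain has positive counts in every sample; "
            "add a pseudocount or drop sparse samples")
    sub = mat[positive]
    log_geomean = np.log(sub).mean(axis=1)
    ratios = np.log(sub) - log_geomean[:, None]
    sf = np.exp(np.median(ratios, axis=0))
    return pd.Series(sf, index=counts.columns, name="size_factor")


@dataclass
class DispersionEstimate:
    """Per-strain NB dispersions with a fitted mean trend.

    ``alpha`` is the final per-strain dispersion
    max(method-of-moments estimate, trend value) with trend
    α_tr(μ) = a0 + a1/μ.
    """

    alpha: pd.Series
    base_mean: pd.Series
    raw: pd.Series
    a0: float
    a1: float

    def trend(self, mu: np.ndarray) -> np.ndarray:
        with np.errstate(divide="ignore"):
            t = self.a0 + self.a1 / np.maximum(mu, 1e-12)
        return np.clip(t, 0.0, None)


def estimate_dispersion(counts: pd.DataFrame, sf: pd.Series,
                        groups: Sequence[Sequence[str]]) -> DispersionEstimate:
    """Method-of-moments dispersion per strain, pooled across groups.

    Within each replicate group the sample mean and variance of normalized
    counts are computed; means and variances are averaged across groups and
    α̂ = max(0, (s² − μ)/μ²).  A 1/μ trend is fit by least squares on the
    *unclipped* moment estimates of all strains — fitting only the positive
    estimates would overestimate the trend whenever many estimates clip to
    zero, as they do with two replicates — and the final dispersion is the
    elementwise max of the clipped raw estimate and the trend, a guard
    against per-strain underestimation.
    """
    for g in groups:
        if len(g) < 2:
            raise ParameterError(
                "each group needs >= 2 replicate samples to estimate dispersion")
    q = counts / sf
    means, variances = [], []
    for g in groups:
        sub = q[list(g)].to_numpy(dtype=float)
        means.append(sub.mean(axis=1))
        variances.append(sub.var(axis=1, ddof=1))
    mu = np.mean(means, axis=0)
    s2 = np.mean(variances, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        unclipped = np.where(mu > 0, (s2 - mu) / np.maximum(mu, 1e-12) ** 2, 0.0)
    raw = np.clip(unclipped, 0.0, None)

    use = mu > 0
    if use.sum() >= 2:
        x = 1.0 / mu[use]
        A = np.column_stack([np.ones(use.sum()), x])
        coef, *_ = np.linalg.lstsq(A, unclipped[use], rcond=None)
        a0, a1 = float(coef[0]), float(coef[1])
    else:
        a0, a1 = 0.0, 0.0
    est = DispersionEstimate(
        alpha=pd.Series(raw, index=counts.index),  # placeholder, replaced below
        base_mean=pd.Series(mu, index=counts.index),
        raw=pd.Series(raw, index=counts.index),
        a0=a0, a1=a1,
    )
    final = np.maximum(raw, est.trend(mu))
    est.alpha = pd.Series(final, index=counts.index, name="alpha")
    return est


def bh_fdr(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up: q_(i) = min_{j>=i} min(1, p_(j)·m/j)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ParameterError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum(1.0, np.minimum.accumulate(scaled[::-1])[::-1])
    q = np.empty(m)
    q[order] = q_sorted
    return q


def test_contrast(counts: pd.DataFrame, sf: pd.Series, dispersion: DispersionEstimate,
                  group_a: Sequence[str], group_b: Sequence[str],
                  pseudocount: float = 0.5) -> pd.DataFrame:
    """Wald test of the B-vs-A log2 ratio of group mean normalized counts.

    log2fc = log2((mean_B + c)/(mean_A + c)); the SE follows from the delta
    method with Var(q_ij) = μ/sf_j + α μ²; p is the two-sided normal tail
    of log2fc/se and padj is Benjamini–Hochberg over all strains.  Strains
    with zero counts throughout both groups get log2fc 0 and p 1.
    """
    if len(group_a) == 0 or len(group_b) == 0:
        raise ParameterError("both groups must be non-empty")
    q = counts / sf
    alpha = dispersion.alpha.reindex(counts.index).to_numpy(dtype=float)
    c = pseudocount

    def group_stats(samples: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
        sub = q[list(samples)].to_numpy(dtype=float)
        mean = sub.mean(axis=1)
        mu = mean + c
        inv_sf = (1.0 / sf[list(samples)].to_numpy(dtype=float))
        n = len(samples)
        var_mean = (mu[:, None] * inv_sf[None, :] + alpha[:, None] * mu[:, None] ** 2
                    ).sum(axis=1) / n**2
        var_log2 = var_mean / (mu**2 * LN2**2)
        return mean, var_log2

    mean_a, vlog_a = group_stats(group_a)
    mean_b, vlog_b = group_stats(group_b)
    log2fc = np.log2(mean_b + c) - np.log2(mean_a + c)
    se = np.sqrt(vlog_a + vlog_b)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, log2fc / se, 0.0)
    p = 2.0 * sps.norm.sf(np.abs(z))

    all_zero = (counts[list(group_a) + list(group_b)].to_numpy() == 0).all(axis=1)
    log2fc = np.where(all_zero, 0.0, log2fc)
    p = np.where(all_zero, 1.0, p)

    base_mean = np.concatenate([mean_a[None], mean_b[None]]).mean(axis=0)
    out = pd.DataFrame({
        "baseMean": base_mean,
        "log2fc": log2fc,
        "se": se,
        "p": p,
        "padj": bh_fdr(p),
        "call": "NS",
    }, index=counts.index)
    return out


def classify(results: pd.DataFrame, alpha_sig: float = 0.05,
             fold: float = 1.5) -> pd.DataFrame:
    """Fill HP/HI/NS calls: significant (raw p < alpha_sig) and at least a
    ``fold``-fold change in the corresponding direction."""
    if fold <= 1.0:
        raise ParameterError(f"fold threshold must exceed 1, got {fold}")
    theta = np.log2(fold)
    out = results.copy()
    hp = (out["log2fc"] >= theta) & (out["p"] < alpha_sig)
    hi = (out["log2fc"] <= -theta) & (out["p"] < alpha_sig)
    out["call"] = np.where(hp, "HP", np.where(hi, "HI", "NS"))
    return out


def run_contrast(counts: pd.DataFrame, group_a: Sequence[str], group_b: Sequence[str],
                 alpha_sig: float = 0.05, fold: float = 1.5,
                 pseudocount: float = 0.5) -> pd.DataFrame:
    """Size factors + dispersion + Wald test + classification in one call.

    Size factors and dispersions are estimated from the contrast's own
    samples, so the result is invariant to rescaling any single sample.
    """
    used = list(group_a) + list(group_b)
    sub = counts[used]
    sf = size_factors(sub)
    disp = estimate_dispersion(sub, sf, [group_a, group_b])
    res = test_contrast(sub, sf, disp, group_a, group_b, pseudocount=pseudocount)
    return classify(res, alpha_sig=alpha_sig, fold=fold)


def intersect_calls(call_sets: Mapping[str, set[str]]) -> pd.DataFrame:
    """UpSet-style tabulation of strains shared between per-condition calls.

    For every non-empty subset of conditions, counts the strains called in
    exactly that subset.  Rows are ordered by subset size then condition
    order; the ``conditions`` column joins member names with '+'.
    """
    names = list(call_sets)
    if len(names) < 2:
        raise ParameterError("need at least two conditions to intersect")
    membership: dict[str, frozenset[str]] = {}
    for cond, strains in call_sets.items():
        for s in strains:
            membership[s] = membership.get(s, frozenset()) | {cond}
    rows = []
    for size in range(1, len(names) + 1):
        for subset in combinations(names, size):
            key = frozenset(subset)
            n = sum(1 for mem in membership.values() if mem == key)
            rows.append(("+".join(subset), size, n))
    return pd.DataFrame(rows, columns=["conditions", "degree", "count"])
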