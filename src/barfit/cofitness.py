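"""Co-fitness analysis: shared fitness patterns across conditions.

Strains with similar fitness profiles across environments plausibly act in
related processes.  Profiles are the log2 fold changes from the eight
stage comparisons {batch>pool, late>early steady state} × {C-limited,
N-limited} × {30 °C, 36 °C}.  Strains responsive to at least one design
variable (per-strain linear model) are clustered by partitioning around
medoids (PAM, BUILD + SWAP), and each cluster is tested for enrichment of
the SUT and CUT ncRNA classes with an exact binomial test and BH FDR.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.metrics import silhouette_score

from barfit.errors import ParameterError, ValidationError
from barfit.fitness import bh_fdr  # noqa: F401  (part of this module's surface)

#: canonical column order: phase (B>P then L>E), nutrient (C then N), temp
COMPARISONS = (
    "BP_Clim30", "BP_Clim36", "BP_Nlim30", "BP_Nlim36",
    "LE_Clim30", "LE_Clim36", "LE_Nlim30", "LE_Nlim36",
)

#: optional 12-column layout including the LiCl conditions
COMPARISONS_WITH_LICL = COMPARISONS + (
    "BP_Clim30LiCl", "BP_Nlim30LiCl", "LE_Clim30LiCl", "LE_Nlim30LiCl",
)


def comparison_covariates(columns: Sequence[str]) -> pd.DataFrame:
    """Design covariates for each comparison column.

    phase: B>P = 0, L>E = 1; nutrient: C = 0, N = 1; temperature:
    30 °C = 0, 36 °C = 1 (LiCl columns code as 30 °C).
    """
    rows = []
    for c in columns:
        phase = 0 if c.startswith("BP") else 1
        nutrient = 0 if "Clim" in c else 1
        temp = 1 if "36" in c else 0
        rows.append((phase, nutrient, temp))
    return pd.DataFrame(rows, index=list(columns),
                        columns=["phase", "nutrient", "temperature"])


def build_profiles(contrasts: Mapping[str, pd.DataFrame],
                   columns: Sequence[str] = COMPARISONS,
                   ) -> tuple[pd.DataFrame, int]:
    """Assemble the strain × comparison log2fc matrix.

    Only strains present in every comparison are kept; the number dropped
    is returned alongside.  Column order is canonical regardless of the
    mapping's order.
    """
    missing = [c for c in columns if c not in contrasts]
    if missing:
        raise ValidationError(f"missing comparison(s): {missing}")
    series = {c: contrasts[c]["log2fc"] for c in columns}
    common = None
    for s in series.values():
        idx = set(s.index)
        common = idx if common is None else (common & idx)
    all_strains = set().union(*(set(s.index) for s in series.values()))
    keep = sorted(common)
    profiles = pd.DataFrame({c: series[c].loc[keep] for c in columns},
                            index=pd.Index(keep, name="strain_id"))
    return profiles, len(all_strains) - len(keep)


def glm_select(profiles: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Per-strain linear model of the profile on the design covariates.

    Ordinary least squares of the 8 (or 12) log2fc values on coded phase /
    nutrient / temperature covariates with intercept; two-sided p per
    coefficient from the Wald statistic referred to the t distribution on
    the residual degrees of freedom (4 for the 8-column design), keeping
    per-coefficient rates nominal at this small sample size.  A strain is
    retained when any non-intercept coefficient has p ≤ alpha.
    """
    cov = comparison_covariates(profiles.columns)
    X = np.column_stack([np.ones(len(cov)), cov.to_numpy(dtype=float)])
    n_obs, n_par = X.shape
    df_resid = n_obs - n_par
    if df_resid < 1:
        raise ParameterError("degenerate design: no residual degrees of freedom")
    xtx_inv = np.linalg.inv(X.T @ X)
    hat = xtx_inv @ X.T

    Y = profiles.to_numpy(dtype=float)  # strains × comparisons
    betas = Y @ hat.T  # strains × 4
    resid = Y - betas @ X.T
    rss = (resid**2).sum(axis=1)
    sigma2 = rss / df_resid
    se = np.sqrt(np.outer(sigma2, np.diag(xtx_inv)))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, betas / se, np.where(betas != 0, np.inf, 0.0))
    p = 2.0 * sps.t.sf(np.abs(z), df=df_resid)

    names = ["intercept", "phase", "nutrient", "temperature"]
    out = pd.DataFrame(index=profiles.index)
    for k, name in enumerate(names):
        out[f"coef_{name}"] = betas[:, k]
        out[f"p_{name}"] = p[:, k]
    out["retained"] = (p[:, 1:] <= alpha).any(axis=1)
    return out


# ---------------------------------------------------------------------------
# partitioning around medoids


@dataclass
class ClusterSolution:
    """A PAM solution over retained strains."""

    k: int
    assignment: pd.Series  # strain_id → cluster id (1..k)
    medoids: list[str]
    cost: float
    silhouette: float

    def sizes(self) -> pd.Series:
        return self.assignment.value_counts().sort_index()


def _pam_build(D: np.ndarray, k: int) -> list[int]:
    """Greedy BUILD phase; ties broken by lowest index."""
    n = D.shape[0]
    first = int(np.argmin(D.sum(axis=1)))
    medoids = [first]
    dmin = D[:, first].copy()
    while len(medoids) < k:
        # gain of adding candidate h: sum of positive reductions
        reductions = np.clip(dmin[:, None] - D, 0.0, None).sum(axis=0)
        reductions[medoids] = -np.inf
        h = int(np.argmax(reductions))
        medoids.append(h)
        dmin = np.minimum(dmin, D[:, h])
    return medoids


def _pam_swap(D: np.ndarray, medoids: list[int]) -> tuple[list[int], float]:
    """Exhaustive SWAP phase; applies the best strictly improving swap until
    none exists.  Cost is monotonically non-increasing by construction."""
    n = D.shape[0]
    medoids = sorted(medoids)
    cost = float(D[:, medoids].min(axis=1).sum())
    while True:
        best = (0.0, None, None)
        others = [h for h in range(n) if h not in medoids]
        for mi, m in enumerate(medoids):
            rest = medoids[:mi] + medoids[mi + 1:]
            dmin_rest = D[:, rest].min(axis=1) if rest else np.full(n, np.inf)
            # new cost for every candidate h at once
            new_costs = np.minimum(dmin_rest[:, None], D[:, others]).sum(axis=0)
            j = int(np.argmin(new_costs))
            delta = float(new_costs[j]) - cost
            if delta < best[0] - 1e-12:
                best = (delta, m, others[j])
        if best[1] is None:
            return medoids, cost
        _, m_out, h_in = best
        medoids = sorted(set(medoids) - {m_out} | {h_in})
        new_cost = float(D[:, medoids].min(axis=1).sum())
        assert new_cost <= cost + 1e-9, "SWAP must not increase cost"
        cost = new_cost


def pam_cluster(profiles: pd.DataFrame, k: int | None = None,
                k_range: Sequence[int] = range(2, 11)) -> ClusterSolution:
    """PAM (BUILD + SWAP) on Euclidean distances between profile rows.

    With ``k=None`` the cluster count is chosen over ``k_range`` by maximum
    mean silhouette width (ties favour the smaller k).  Deterministic: all
    ties break toward the lowest strain index.
    """
    X = profiles.to_numpy(dtype=float)
    n = X.shape[0]
    diff = X[:, None, :] - X[None, :, :]
    D = np.sqrt((diff**2).sum(axis=2))

    def solve(kk: int) -> tuple[list[int], float, np.ndarray, float]:
        if kk < 2 or kk > n:
            raise ParameterError(f"k must be in [2, {n}], got {kk}")
        med, cost = _pam_swap(D, _pam_build(D, kk))
        labels = np.argmin(D[:, med], axis=1)
        if len(set(labels)) < 2:
            sil = -1.0
        else:
            sil = float(silhouette_score(D, labels, metric="precomputed"))
        return med, cost, labels, sil

    if k is None:
        best = None
        for kk in k_range:
            if kk >= n:
                break
            cand = (kk, *solve(kk))
            if best is None or cand[4] > best[4] + 1e-12:
                best = cand
        if best is None:
            raise ParameterError("no feasible k in k_range")
        k, medoids, cost, labels, sil = best
    else:
        medoids, cost, labels, sil = solve(k)

    assignment = pd.Series(labels + 1, index=profiles.index, name="cluster")
    return ClusterSolution(k=k, assignment=assignment,
                           medoids=[profiles.index[m] for m in medoids],
                           cost=cost, silhouette=sil)


def split_by_direction(profiles: pd.DataFrame, solution: ClusterSolution) -> pd.Series:
    """Sub-cluster id by direction of fitness change: 1 when the strain's
    mean profile value is >= 0 (fitness gain), else 2."""
    mean = profiles.mean(axis=1)
    return pd.Series(np.where(mean >= 0, 1, 2), index=profiles.index, name="subcluster")


# ---------------------------------------------------------------------------
# class enrichment


def binom_test_two_sided(x: int, n: int, p0: float) -> float:
    """Exact binomial two-sided p by tail doubling, capped at 1."""
    if not (0.0 < p0 < 1.0):
        raise ParameterError(f"p0 must be in (0, 1), got {p0}")
    if not (0 <= x <= n):
        raise ParameterError(f"x={x} outside [0, n={n}]")
    lower = sps.binom.cdf(x, n, p0)
    upper = sps.binom.sf(x - 1, n, p0)
    return float(min(1.0, 2.0 * min(lower, upper)))


def enrichment(solution: ClusterSolution, classes: Mapping[str, str],
               tested_classes: Sequence[str] = ("SUT", "CUT")) -> pd.DataFrame:
    """Exact binomial SUT/CUT enrichment per cluster with BH FDR.

    The background proportion p0 of each class is its frequency among all
    clustered strains; clusters with every strain or no strain of a class
    background (p0 outside (0,1)) contribute no row for that class.
    """
    labels = solution.assignment
    strains = list(labels.index)
    missing = [s for s in strains if s not in classes]
    if missing:
        raise ValidationError(f"no class label for strains: {missing[:5]}")
    cls = pd.Series({s: classes[s] for s in strains})
    rows = []
    for c in tested_classes:
        p0 = float((cls == c).mean())
        if not (0.0 < p0 < 1.0):
            continue
        for cid in sorted(labels.unique()):
            members = labels.index[labels == cid]
            n = len(members)
            if n == 0:
                continue
            x = int((cls.loc[members] == c).sum())
            rows.append((int(cid), c, x, n, p0, binom_test_two_sided(x, n, p0)))
    out = pd.DataFrame(rows, columns=["cluster", "class", "x", "n", "p0", "p_binomial"])
    out["q"] = bh_fdr(out["p_binomial"].to_numpy()) if len(out) else []
    return out
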