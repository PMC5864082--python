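"""Arrayed colony-size screen and monoculture growth curves.

Haploid deletion strains stamped in a grid onto solid media give one
colony size per position.  Sizes are normalized per plate (scale to the
plate median, then one round of multiplicative row/column median polish to
cancel positional effects), replicates are averaged, and the distribution
of normalized sizes is modelled as a two-component normal mixture — a
majority normal-growth class plus a reduced-fitness class — fit by EM.
Each strain is scored against the component closer to the wild-type mean:
p = 2(1 − Φ(|v − μ_wt|/σ_wt)), significant at p < 0.05.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from barfit.errors import ParameterError, ValidationError


@dataclass
class PlateGrid:
    """One plate: colony sizes, strain layout and wild-type positions."""

    plate_id: str
    sizes: np.ndarray  # rows × cols, NaN = absent colony
    strain_ids: np.ndarray  # object array, "" = empty position
    wt_positions: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sizes = np.asarray(self.sizes, dtype=float)
        if self.sizes.ndim != 2 or min(self.sizes.shape) < 2:
            raise ParameterError(
                f"plate {self.plate_id}: grid must be at least 2x2")
        if self.strain_ids.shape != self.sizes.shape:
            raise ValidationError(f"plate {self.plate_id}: layout/size shape mismatch")
        nr, nc = self.sizes.shape
        for r, c in self.wt_positions:
            if not (0 <= r < nr and 0 <= c < nc):
                raise ValidationError(
                    f"plate {self.plate_id}: wild-type position ({r},{c}) out of bounds")


def _polish(grid: np.ndarray) -> np.ndarray:
    """Scale to plate median, then one round of row/column median polish
    (multiplicative)."""
    med = np.nanmedian(grid)
    if not np.isfinite(med) or med <= 0:
        raise ValidationError("plate has no positive colony sizes")
    out = grid / med
    with warnings.catch_warnings():
        # rows/columns that are entirely missing yield NaN medians; keep them
        warnings.simplefilter("ignore", RuntimeWarning)
        row_med = np.nanmedian(out, axis=1, keepdims=True)
        row_med = np.where(np.isfinite(row_med) & (row_med > 0), row_med, 1.0)
        out = out / row_med
        col_med = np.nanmedian(out, axis=0, keepdims=True)
        col_med = np.where(np.isfinite(col_med) & (col_med > 0), col_med, 1.0)
    return out / col_med


def normalize_plates(plates: Sequence[PlateGrid]) -> tuple[pd.Series, float]:
    """Normalize plates and average replicate colonies per strain.

    Returns ``(values, wt_mean)``: the per-strain mean normalized size and
    the mean over wild-type control colonies (the global median when no
    controls are marked).  Missing colonies are ignored in the averages.
    """
    if len(plates) == 0:
        raise ParameterError("need at least one plate")
    per_strain: dict[str, list[float]] = {}
    wt_values: list[float] = []
    for plate in plates:
        if np.all(~np.isfinite(plate.sizes)):
            raise ValidationError(f"plate {plate.plate_id}: all colonies missing")
        norm = _polish(plate.sizes)
        wt_set = set(plate.wt_positions)
        nr, nc = norm.shape
        for r in range(nr):
            for c in range(nc):
                v = norm[r, c]
                if not np.isfinite(v):
                    continue
                if (r, c) in wt_set:
                    wt_values.append(float(v))
                    continue
                sid = plate.strain_ids[r, c]
                if sid:
                    per_strain.setdefault(str(sid), []).append(float(v))
    values = pd.Series({s: float(np.mean(v)) for s, v in sorted(per_strain.items())},
                       name="normalized_size")
    wt_mean = float(np.mean(wt_values)) if wt_values else float(np.median(values))
    return values, wt_mean


# ---------------------------------------------------------------------------
# two-component normal mixture


@dataclass
class MixtureFit:
    """Two-component normal mixture parameters from EM."""

    pi: float  # weight of component 1
    mu1: float
    sigma1: float
    mu2: float
    sigma2: float
    loglik: float
    iterations: int
    converged: bool
    loglik_trace: list[float] = field(default_factory=list)

    def wt_component(self, wt_mean: float) -> tuple[float, float]:
        """(μ, σ) of the component whose mean is nearer the wild-type."""
        if abs(self.mu1 - wt_mean) <= abs(self.mu2 - wt_mean):
            return self.mu1, self.sigma1
        return self.mu2, self.sigma2


def fit_mixture(values: Sequence[float], max_iter: int = 1000, tol: float = 1e-8,
                sigma_floor: float = 1e-3) -> MixtureFit:
    """Standard EM for a two-component normal mixture.

    Initialization splits the data at its 10th percentile (component 2 =
    the lower tail, the presumptive reduced-fitness class).  Convergence
    when the log-likelihood gain falls below ``tol``; standard deviations
    are clamped at ``sigma_floor``.  Non-convergence is flagged, not
    raised.  The log-likelihood trace is non-decreasing (EM guarantee,
    asserted).
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 10:
        raise ParameterError(f"need >= 10 finite values, got {x.size}")

    if np.ptp(x) == 0.0:
        # degenerate: all values identical
        mu = float(x.mean())
        return MixtureFit(pi=0.5, mu1=mu, sigma1=sigma_floor, mu2=mu,
                          sigma2=sigma_floor, loglik=float(
                              np.sum(sps.norm.logpdf(x, mu, sigma_floor))),
                          iterations=0, converged=True, loglik_trace=[])
    q10 = np.quantile(x, 0.10)
    low = x <= q10
    if low.all():
        low = x < np.max(x)

    def mstats(sub: np.ndarray) -> tuple[float, float]:
        return float(sub.mean()), float(max(sub.std(), sigma_floor))

    mu1, s1 = mstats(x[~low])
    mu2, s2 = mstats(x[low])
    pi = float((~low).mean())
    pi = min(max(pi, 1e-6), 1 - 1e-6)

    trace: list[float] = []
    prev = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # E step
        log_p1 = np.log(pi) + sps.norm.logpdf(x, mu1, s1)
        log_p2 = np.log1p(-pi) + sps.norm.logpdf(x, mu2, s2)
        m = np.maximum(log_p1, log_p2)
        log_tot = m + np.log(np.exp(log_p1 - m) + np.exp(log_p2 - m))
        loglik = float(log_tot.sum())
        assert loglik >= prev - 1e-6, "EM log-likelihood must be non-decreasing"
        trace.append(loglik)
        if loglik - prev < tol:
            converged = True
            break
        prev = loglik
        r1 = np.exp(log_p1 - log_tot)
        # M step
        w1 = r1.sum()
        w2 = x.size - w1
        pi = min(max(float(w1 / x.size), 1e-6), 1 - 1e-6)
        mu1 = float((r1 * x).sum() / max(w1, 1e-12))
        mu2 = float(((1 - r1) * x).sum() / max(w2, 1e-12))
        s1 = float(max(np.sqrt((r1 * (x - mu1) ** 2).sum() / max(w1, 1e-12)), sigma_floor))
        s2 = float(max(np.sqrt(((1 - r1) * (x - mu2) ** 2).sum() / max(w2, 1e-12)), sigma_floor))

    return MixtureFit(pi=pi, mu1=mu1, sigma1=s1, mu2=mu2, sigma2=s2,
                      loglik=trace[-1], iterations=it, converged=converged,
                      loglik_trace=trace)


def score_strains(fit: MixtureFit, values: pd.Series, wt_mean: float,
                  alpha: float = 0.05, two_sided: bool = True) -> pd.DataFrame:
    """Score strains against the wild-type-proximal mixture component.

    p = 2(1 − Φ(|v − μ_wt| / σ_wt)) (halved for the one-sided option);
    significant strictly below ``alpha``; direction is the sign of
    v − μ_wt for significant strains, 'none' otherwise.
    """
    mu, sigma = fit.wt_component(wt_mean)
    v = values.to_numpy(dtype=float)
    z = (v - mu) / sigma
    p = 2.0 * sps.norm.sf(np.abs(z))
    if not two_sided:
        p = p / 2.0
    significant = p < alpha
    direction = np.where(~significant, "none", np.where(v > mu, "bigger", "smaller"))
    return pd.DataFrame({
        "normalized_size": v,
        "p": p,
        "significant": significant,
        "direction": direction,
    }, index=values.index)


# ---------------------------------------------------------------------------
# plate TSV I/O (columns: plate_id, row, col, strain_id, size, is_wt)


def write_plates_tsv(plates: Sequence[PlateGrid], path, header_comment: str | None = None
                     ) -> None:
    with open(path, "wt", newline="\n") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        fh.write("plate_id\trow\tcol\tstrain_id\tsize\tis_wt\n")
        for plate in plates:
            wt_set = set(plate.wt_positions)
            nr, nc = plate.sizes.shape
            for r in range(nr):
                for c in range(nc):
                    v = plate.sizes[r, c]
                    size = f"{v:.6g}" if np.isfinite(v) else "NA"
                    fh.write(f"{plate.plate_id}\t{r}\t{c}\t{plate.strain_ids[r, c]}"
                             f"\t{size}\t{int((r, c) in wt_set)}\n")


def read_plates_tsv(path) -> list[PlateGrid]:
    df = pd.read_csv(path, sep="\t", comment="#", na_values=["NA"],
                     dtype={"strain_id": str}, keep_default_na=False)
    missing = {"plate_id", "row", "col", "strain_id", "size", "is_wt"} - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing plate column(s) {sorted(missing)}")
    df["size"] = pd.to_numeric(df["size"], errors="coerce")
    plates = []
    for pid, sub in df.groupby("plate_id", sort=True):
        nr, nc = int(sub["row"].max()) + 1, int(sub["col"].max()) + 1
        sizes = np.full((max(nr, 2), max(nc, 2)), np.nan)
        names = np.full(sizes.shape, "", dtype=object)
        wt = []
        for _, row in sub.iterrows():
            r, c = int(row["row"]), int(row["col"])
            sizes[r, c] = row["size"]
            names[r, c] = row["strain_id"]
            if int(row["is_wt"]):
                wt.append((r, c))
        plates.append(PlateGrid(plate_id=str(pid), sizes=sizes, strain_ids=names,
                                wt_positions=wt))
    return plates


# ---------------------------------------------------------------------------
# monoculture growth curves


@dataclass
class GrowthCurve:
    """OD time series from a plate-reader monoculture assay."""

    times: np.ndarray  # hours, strictly increasing
    od: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.od = np.asarray(self.od, dtype=float)
        if self.times.size != self.od.size:
            raise ValidationError("times and OD must have equal length")
        if self.times.size < 2:
            raise ParameterError("a growth curve needs at least 2 points")
        if np.any(np.diff(self.times) <= 0):
            raise ValidationError("times must be strictly increasing")


def growth_auc(curve: GrowthCurve) -> float:
    """Area under the OD curve (trapezoidal rule), in OD·hours."""
    return float(np.trapezoid(curve.od, curve.times))
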