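"""Single-trait QTL machinery on a recombination-bin map.

The scan is composite interval mapping in regression form: at each bin the
LOD score is (n/2) * log10(RSS_reduced / RSS_full), where the full model is
intercept + retained marker covariates + the test-bin genotype and the
reduced model drops the test-bin genotype.  On a sequencing-derived bin map
genotypes are effectively fully informative, so the regression LOD
coincides with the interval-mapping mixture likelihood; scan positions are
the bins themselves (the map is already ultra-dense, pseudomarkers add
nothing).

Marker covariates are chosen by greedy forward least squares and, at each
test position, covariates within half the scan window (genetic distance,
same chromosome) are dropped from BOTH models so the local effect is not
absorbed.  Genome-wide significance comes from a global permutation test:
line labels of the trait are shuffled, the genome-wide maximum LOD of each
permuted scan is recorded, and the threshold is the (1 - alpha) quantile of
the pooled maxima.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .datamodel import BinMap, ExpressionSet, GenotypeMatrix

log = logging.getLogger("eqtlnet")

_EPS = 1e-12


@dataclass
class ScanSettings:
    """Tunables of the scan.

    n_covariates
        marker covariates for composite interval mapping (default 5).
    window_cm
        scan window; covariates within window_cm / 2 of the test position
        (genetic distance, same chromosome) are excluded (default 10 cM).
    lod_threshold_e / lod_threshold_p
        declaration thresholds for expression and phenotypic QTLs.  The
        expression default (4.95) is the permutation-calibrated genome-wide
        0.05 value for the emulated study; phenotypes use 5.0.
    si_drop
        LOD drop defining the support interval (default 1.5).
    n_perm, perm_sample_size, alpha
        permutation-test shape: how many permutations per sampled trait,
        how many e-traits are sampled, and the genome-wide error rate.
    reselect_covariates
        re-run covariate selection inside every permutation replicate
        (conservative; mirrors rerunning the whole scan per permutation).
    """

    n_covariates: int = 5
    window_cm: float = 10.0
    lod_threshold_e: float = 4.95
    lod_threshold_p: float = 5.0
    si_drop: float = 1.5
    n_perm: int = 1000
    perm_sample_size: int = 100
    alpha: float = 0.05
    reselect_covariates: bool = True

    def __post_init__(self):
        if self.si_drop <= 0:
            raise ValueError("si_drop must be positive")
        if self.window_cm <= 0 or self.alpha <= 0 or self.alpha >= 1:
            raise ValueError("window_cm and alpha must be positive (alpha < 1)")


@dataclass
class LodProfile:
    """Genome-wide LOD curve for one trait."""

    binmap: BinMap
    lod: np.ndarray
    covariates: List[int] = field(default_factory=list)
    retained: Optional[np.ndarray] = None  # covariates kept at each position

    def to_frame(self) -> pd.DataFrame:
        t = self.binmap.table
        return pd.DataFrame(
            {
                "bin_id": t["bin_id"],
                "chrom": t["chrom"],
                "cM": t["genetic_pos"],
                "LOD": self.lod,
            }
        )

    def peak_index(self, chrom=None) -> int:
        if chrom is None:
            return int(np.argmax(self.lod))
        mask = (self.binmap.table["chrom"] == chrom).to_numpy()
        idx = np.flatnonzero(mask)
        return int(idx[np.argmax(self.lod[idx])])


def _as_numeric(G: Union[GenotypeMatrix, np.ndarray]) -> np.ndarray:
    return G.numeric() if isinstance(G, GenotypeMatrix) else np.asarray(G, dtype=float)


def select_covariates(
    y: Sequence[float], G: Union[GenotypeMatrix, np.ndarray], k: int
) -> List[int]:
    """Greedy forward least-squares selection of k marker covariates.

    At each step the bin giving the largest reduction in residual sum of
    squares is added (Gram-Schmidt update).  Missing genotype calls are
    mean-imputed for selection only; lines with missing trait values are
    dropped.  Returns bin indices in selection order.
    """
    y = np.asarray(y, dtype=float)
    X = _as_numeric(G)
    keep = ~np.isnan(y)
    y, X = y[keep], X[keep]
    n = len(y)
    if k == 0:
        return []
    if k >= n - 2:
        raise ValueError(f"cannot select {k} covariates from {n} complete lines")

    col_mean = np.nanmean(X, axis=0)
    col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
    X = np.where(np.isnan(X), col_mean, X)

    r = y - y.mean()
    Xc = X - X.mean(axis=0)
    chosen: List[int] = []
    for _ in range(k):
        den = (Xc**2).sum(axis=0)
        num = Xc.T @ r
        score = np.where(den > 1e-10, num**2 / np.maximum(den, _EPS), -np.inf)
        if chosen:
            score[chosen] = -np.inf
        j = int(np.argmax(score))
        if not np.isfinite(score[j]) or score[j] <= 0:
            break
        chosen.append(j)
        xj = Xc[:, j].copy()
        nrm = xj @ xj
        r = r - xj * (xj @ r) / nrm
        Xc = Xc - np.outer(xj, (xj @ Xc) / nrm)
    return chosen


def _retained_mask(binmap: BinMap, covariates: Sequence[int], window_cm: float) -> np.ndarray:
    """(n_cov, n_bins) bool: covariate retained at each test position.

    A covariate is dropped where it sits on the same chromosome within
    window_cm / 2 (genetic distance) of the test bin.
    """
    t = binmap.table
    cm = t["genetic_pos"].to_numpy()
    chrom = t["chrom"].to_numpy()
    half = window_cm / 2.0
    masks = np.ones((len(covariates), binmap.n_bins), dtype=bool)
    for i, c in enumerate(covariates):
        near = (chrom == chrom[c]) & (np.abs(cm - cm[c]) <= half)
        masks[i, near] = False
    return masks


def _ols_residual(M: np.ndarray, Z: np.ndarray) -> np.ndarray:
    coef, *_ = np.linalg.lstsq(Z, M, rcond=None)
    return M - Z @ coef


def cim_scan(
    y: Sequence[float],
    G: Union[GenotypeMatrix, np.ndarray],
    binmap: BinMap,
    settings: Optional[ScanSettings] = None,
    covariates: Optional[Sequence[int]] = None,
) -> LodProfile:
    """Composite-interval-mapping LOD profile over all bins.

    Genotypes are coded A -> -1, B -> +1; heterozygous or missing calls are
    excluded pairwise at each test position.  Bins with no genotype variance
    get LOD 0 with a warning.
    """
    settings = settings or ScanSettings()
    y = np.asarray(y, dtype=float)
    X = _as_numeric(G)
    if X.shape[1] != binmap.n_bins:
        raise ValueError("genotype columns do not match the bin map")
    if covariates is None:
        covariates = (
            select_covariates(y, X, settings.n_covariates)
            if settings.n_covariates > 0
            else []
        )
    covariates = list(covariates)
    masks = _retained_mask(binmap, covariates, settings.window_cm)
    retained_counts = masks.sum(axis=0) if covariates else np.zeros(binmap.n_bins, dtype=int)

    lod = np.zeros(binmap.n_bins)
    complete = ~(np.isnan(y) | np.isnan(X).any(axis=1))
    if complete.all():
        _scan_fast(y, X, masks, covariates, lod)
    else:
        _scan_pairwise(y, X, masks, covariates, lod)
    return LodProfile(binmap=binmap, lod=lod, covariates=covariates, retained=retained_counts)


def _scan_fast(y, X, masks, covariates, lod):
    n = len(y)
    groups: dict = {}
    if covariates:
        for b in range(X.shape[1]):
            key = tuple(np.flatnonzero(masks[:, b]))
            groups.setdefault(key, []).append(b)
    else:
        groups[()] = list(range(X.shape[1]))
    ones = np.ones((n, 1))
    for key, bins in groups.items():
        Z = np.column_stack([ones] + [X[:, covariates[i]] for i in key]) if key else ones
        yr = _ols_residual(y, Z)
        rss0 = float(yr @ yr)
        B = np.asarray(bins)
        Xr = _ols_residual(X[:, B], Z)
        den = (Xr**2).sum(axis=0)
        num = Xr.T @ yr
        if rss0 <= _EPS:
            lod[B] = 0.0
            continue
        degenerate = den <= 1e-10
        if degenerate.any():
            log.warning("%d bins have no genotype variance after covariates; LOD set to 0",
                        int(degenerate.sum()))
        rss1 = rss0 - np.where(degenerate, 0.0, num**2 / np.maximum(den, _EPS))
        rss1 = np.maximum(rss1, _EPS * rss0)
        lod[B] = np.maximum((n / 2.0) * np.log10(rss0 / rss1), 0.0)


def _scan_pairwise(y, X, masks, covariates, lod):
    col_mean = np.nanmean(X, axis=0)
    col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
    for b in range(X.shape[1]):
        x = X[:, b]
        keep = ~(np.isnan(y) | np.isnan(x))
        n = int(keep.sum())
        if n < 4:
            continue
        cols = [covariates[i] for i in np.flatnonzero(masks[:, b])] if covariates else []
        C = X[np.ix_(keep, cols)] if cols else np.empty((n, 0))
        C = np.where(np.isnan(C), col_mean[cols], C) if cols else C
        Z = np.column_stack([np.ones(n), C])
        yr = _ols_residual(y[keep], Z)
        rss0 = float(yr @ yr)
        xr = _ols_residual(x[keep], Z)
        den = float(xr @ xr)
        if rss0 <= _EPS:
            continue
        if den <= 1e-10:
            log.warning("bin %d: no genotype variance; LOD set to 0", b)
            continue
        rss1 = max(rss0 - (xr @ yr) ** 2 / den, _EPS * rss0)
        lod[b] = max((n / 2.0) * np.log10(rss0 / rss1), 0.0)


def permutation_threshold(
    E: Union[ExpressionSet, np.ndarray],
    G: Union[GenotypeMatrix, np.ndarray],
    binmap: BinMap,
    settings: Optional[ScanSettings] = None,
    seed: int = 0,
) -> float:
    """Global permutation threshold for genome-wide significance.

    Samples ``perm_sample_size`` e-traits without replacement; for each,
    permutes the line labels of the trait ``n_perm`` times (genotypes
    fixed), rescans, and records the genome-wide maximum LOD.  The
    threshold is the (1 - alpha) quantile of all pooled maxima.
    """
    settings = settings or ScanSettings()
    if settings.n_perm < 20:
        raise ValueError("n_perm < 20 gives an unstable quantile")
    rng = np.random.default_rng(seed)
    V = E.values.to_numpy() if isinstance(E, ExpressionSet) else np.asarray(E, dtype=float)
    X = _as_numeric(G)
    m = V.shape[0]
    size = settings.perm_sample_size
    if m < size:
        log.warning("only %d e-traits available; using all for the permutation test", m)
        size = m
    sample = rng.choice(m, size=size, replace=False)

    maxima = np.empty(size * settings.n_perm)
    pos = 0
    for g in sample:
        y = V[g]
        base_cov = None
        if not settings.reselect_covariates and settings.n_covariates > 0:
            base_cov = select_covariates(y, X, settings.n_covariates)
        for _ in range(settings.n_perm):
            yp = rng.permutation(y)
            cov = base_cov
            if settings.reselect_covariates and settings.n_covariates > 0:
                cov = select_covariates(yp, X, settings.n_covariates)
            prof = cim_scan(yp, X, binmap, settings, covariates=cov or [])
            maxima[pos] = prof.lod.max()
            pos += 1
    return float(np.quantile(maxima, 1.0 - settings.alpha))


def support_interval(profile: LodProfile, peak: int, drop: float = 1.5) -> Tuple[int, int]:
    """LOD-drop support interval around a peak bin, in bp.

    Walk left and right from the peak, retaining bins while their LOD stays
    at or above LOD(peak) - drop; stop at the first bin below the drop or
    the chromosome end.  Returns (phys_start of leftmost retained bin,
    phys_end of rightmost retained bin).
    """
    t = profile.binmap.table
    chrom = t["chrom"].iloc[peak]
    idx = np.flatnonzero((t["chrom"] == chrom).to_numpy())
    j = int(np.flatnonzero(idx == peak)[0])
    thr = profile.lod[peak] - drop
    lo = j
    while lo - 1 >= 0 and profile.lod[idx[lo - 1]] >= thr:
        lo -= 1
    hi = j
    while hi + 1 < len(idx) and profile.lod[idx[hi + 1]] >= thr:
        hi += 1
    return int(t["phys_start"].iloc[idx[lo]]), int(t["phys_end"].iloc[idx[hi]])


def qtl_effects(y: Sequence[float], g_peak: Sequence[float]) -> Tuple[float, float]:
    """Additive effect and variance explained at the peak marker.

    additive = (mean of parent-2 homozygotes - mean of parent-1
    homozygotes) / 2; var_explained is the R^2 of the marginal
    single-marker regression.  Lines with missing calls are dropped
    pairwise; both genotype classes must be present.
    """
    y = np.asarray(y, dtype=float)
    g = np.asarray(g_peak, dtype=float)
    keep = ~(np.isnan(y) | np.isnan(g))
    y, g = y[keep], g[keep]
    a_mask, b_mask = g < 0, g > 0
    if not a_mask.any() or not b_mask.any():
        raise ValueError("both genotype classes must be present at the peak")
    additive = (y[b_mask].mean() - y[a_mask].mean()) / 2.0
    if y.std() == 0 or g.std() == 0:
        return float(additive), 0.0
    r = np.corrcoef(y, g)[0, 1]
    return float(additive), float(r**2)
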