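"""Ordination of simulation outputs and bloom-signature detection.

Two ordinations mirror the standard exploratory analysis of the index
and allele tables: a PCA (SVD of the centred, unit-variance-scaled index
matrix) and a non-metric multidimensional scaling of the binomial
distance matrix (SMACOF majorization with monotone regression, Kruskal
stress-1, multiple random starts).

The bloom signature operationalises the three-stage course of genotypic
diversity R across a bloom: (1) an early drop as density explodes while
genotype number lags, (2) a slow rise from new mutant/recombinant MLGs
capped by the mid-bloom sex spike, and (3) a drift-driven decay over the
second half of the bloom.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import linregress
from sklearn.isotonic import IsotonicRegression

__all__ = [
    "PCAResult",
    "NMDSResult",
    "SignatureReport",
    "pca_indices",
    "nmds",
    "bloom_signature",
    "h_trend",
]


# ---------------------------------------------------------------------------
# PCA of the index matrix


@dataclass
class PCAResult:
    scores: pd.DataFrame
    loadings: pd.DataFrame
    variance_fraction: np.ndarray


def pca_indices(m: pd.DataFrame, scale: bool = True) -> PCAResult:
    """PCA of an index matrix (rows = days, columns = indices) via SVD.

    Columns are centred and, by default, scaled to unit variance (the
    indices have incommensurate scales); a constant column carries no
    information and is dropped with a warning.  Scores are the day
    coordinates, loadings the index contributions, and the variance
    fractions sum to one.
    """
    if m.shape[0] < 3:
        raise ValueError("need at least 3 rows")
    x = m.to_numpy(dtype=float)
    sd = x.std(axis=0, ddof=1)
    keep = sd > 0
    if not keep.all():
        dropped = list(m.columns[~keep])
        warnings.warn(f"dropping zero-variance columns: {dropped}")
    cols = list(m.columns[keep])
    x = x[:, keep]
    x = x - x.mean(axis=0)
    if scale:
        x = x / x.std(axis=0, ddof=1)
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    # deterministic sign: largest-magnitude loading of each component positive
    signs = np.sign(vt[np.arange(vt.shape[0]), np.abs(vt).argmax(axis=1)])
    signs[signs == 0] = 1.0
    u, vt = u * signs, vt * signs[:, None]
    pcs = [f"PC{i + 1}" for i in range(len(s))]
    scores = pd.DataFrame(u * s, index=m.index, columns=pcs)
    loadings = pd.DataFrame(vt.T, index=cols, columns=pcs)
    var = s**2 / np.sum(s**2)
    return PCAResult(scores=scores, loadings=loadings, variance_fraction=var)


# ---------------------------------------------------------------------------
# non-metric MDS


@dataclass
class NMDSResult:
    coords: np.ndarray
    stress: float
    converged: bool
    stress_history: np.ndarray  # per-iteration stress-1 of the best start


def _nmds_single(
    diss: np.ndarray, n: int, dims: int, max_iter: int, tol: float, rng: np.random.Generator
) -> tuple[np.ndarray, float, bool, np.ndarray]:
    iu = np.triu_indices(n, k=1)
    x = rng.normal(size=(n, dims))
    ir = IsotonicRegression()
    history = []
    prev = np.inf
    converged = False
    for _ in range(max_iter):
        d = pdist(x)
        # monotone regression of configuration distances on dissimilarity rank
        dhat = ir.fit_transform(diss, d)
        denom = float(np.sum(dhat**2))
        if denom > 0:
            dhat = dhat * np.sqrt(np.sum(d**2) / denom)
        ssd = float(np.sum(d**2))
        stress = np.sqrt(np.sum((d - dhat) ** 2) / ssd) if ssd > 0 else 0.0
        history.append(stress)
        if prev - stress < tol:
            converged = True
            break
        prev = stress
        # Guttman transform
        ratio = np.zeros_like(d)
        nz = d > 0
        ratio[nz] = dhat[nz] / d[nz]
        b = np.zeros((n, n))
        b[iu] = -ratio
        b = b + b.T
        np.fill_diagonal(b, -b.sum(axis=1))
        x = b @ x / n
    return x, history[-1], converged, np.asarray(history)


def nmds(
    d: pd.DataFrame | np.ndarray,
    dims: int = 2,
    n_starts: int = 20,
    max_iter: int = 300,
    tol: float = 1e-7,
    seed: int = 0,
) -> NMDSResult:
    """Non-metric MDS of a distance matrix by Kruskal stress-1 minimization.

    Runs SMACOF with isotonic (monotone) regression from ``n_starts``
    random configurations and returns the lowest-stress embedding.  Stress
    is Kruskal's stress-1,
    ``sqrt(sum (d_ij - dhat_ij)^2 / sum d_ij^2)`` over configuration
    distances d and disparities dhat.  Deterministic given ``seed``.  If
    no start converges within ``max_iter`` the best configuration so far
    is returned with ``converged=False``.
    """
    dm = d.to_numpy(dtype=float) if isinstance(d, pd.DataFrame) else np.asarray(d, dtype=float)
    if dm.ndim != 2 or dm.shape[0] != dm.shape[1]:
        raise ValueError("need a square distance matrix")
    if not np.allclose(dm, dm.T):
        raise ValueError("distance matrix must be symmetric")
    n = dm.shape[0]
    diss = dm[np.triu_indices(n, k=1)]
    rng = np.random.default_rng(seed)
    best: tuple | None = None
    for _ in range(n_starts):
        x, stress, conv, hist = _nmds_single(diss, n, dims, max_iter, tol, rng)
        if best is None or stress < best[1]:
            best = (x, stress, conv, hist)
    x, stress, conv, hist = best
    if not conv:
        warnings.warn("nMDS did not converge; returning best configuration so far")
    return NMDSResult(coords=x - x.mean(axis=0), stress=stress, converged=conv, stress_history=hist)


# ---------------------------------------------------------------------------
# bloom signature


@dataclass
class SignatureReport:
    """Boolean three-stage signature flags with their effect sizes.

    Effects: stage1 = pre-bloom R minus the early-bloom minimum; stage2
    and stage3 = least-squares slopes of R per day; sex spike = R change
    across the sex day.
    """

    stage1_drop: bool
    stage2_rise: bool
    sex_spike: bool
    stage3_decay: bool
    effects: dict = field(default_factory=dict)

    @property
    def all_stages(self) -> bool:
        return self.stage1_drop and self.stage2_rise and self.sex_spike and self.stage3_decay


def _slope(days: np.ndarray, values: np.ndarray) -> float:
    if len(days) < 2:
        raise ValueError("need at least two points for a slope")
    return float(linregress(days, values).slope)


def bloom_signature(
    r_series: pd.Series,
    bloom_first_day: int,
    bloom_len: int,
    sex_day: int = 15,
    sexual: bool = True,
    drop_window: int = 5,
) -> SignatureReport:
    """Detect the three-stage diversity signature in one bloom's R series.

    ``r_series`` is indexed by absolute day and must cover the bloom at
    daily resolution plus the last pre-bloom day.  ``sex_day`` is the
    1-based offset of the sex event within the bloom; ``sexual=False``
    (no event occurred) forces ``sex_spike`` to False while the remaining
    stages are still evaluated around the same mid-bloom day.

    Flags: *stage1_drop* — the minimum over the first ``drop_window``
    bloom days falls below the last pre-bloom value; *stage2_rise* —
    positive LS slope from bloom day ``drop_window`` to the day before
    sex; *sex_spike* — R increases from the day before to the day after
    the sex event; *stage3_decay* — non-positive LS slope from two days
    after sex to the bloom end.
    """
    r = r_series.sort_index()
    if r.nunique() <= 1:
        # a flat series carries no signature at all
        return SignatureReport(False, False, False, False, effects={
            "stage1_drop": 0.0, "stage2_slope": 0.0, "sex_spike": 0.0, "stage3_slope": 0.0,
        })
    b0 = bloom_first_day
    sex_abs = b0 + sex_day - 1
    need = [b0 - 1, sex_abs - 1, sex_abs + 1]
    missing = [d for d in need if d not in r.index]
    if missing:
        raise ValueError(f"R series is missing required days {missing}")
    pre = float(r.loc[b0 - 1])
    early = r.loc[b0 : b0 + drop_window - 1]
    if len(early) < drop_window:
        raise ValueError("insufficient within-bloom days (need daily resolution)")
    stage1_effect = pre - float(early.min())
    rise = r.loc[b0 + drop_window - 1 : sex_abs - 1]
    stage2_slope = _slope(rise.index.to_numpy(float), rise.to_numpy(float))
    spike_effect = float(r.loc[sex_abs + 1]) - float(r.loc[sex_abs - 1])
    decay = r.loc[sex_abs + 2 : b0 + bloom_len - 1]
    stage3_slope = _slope(decay.index.to_numpy(float), decay.to_numpy(float))
    return SignatureReport(
        stage1_drop=stage1_effect > 0,
        stage2_rise=stage2_slope > 0,
        sex_spike=bool(sexual and spike_effect > 0),
        stage3_decay=stage3_slope <= 0,
        effects={
            "stage1_drop": stage1_effect,
            "stage2_slope": stage2_slope,
            "sex_spike": spike_effect if sexual else 0.0,
            "stage3_slope": stage3_slope,
        },
    )


def h_trend(metrics: pd.DataFrame) -> tuple[float, float]:
    """Least-squares slope (and standard error) of heterozygosity vs day.

    A positive slope across a whole run is the footprint of recurrent
    sex: bottleneck sampling preferentially removes low-heterozygosity
    clonal lines, so recombining populations creep upward in H while
    obligate clones do not.
    """
    sub = metrics.dropna(subset=["H"])
    if len(sub) < 10:
        raise ValueError("need at least 10 sampling days")
    fit = linregress(sub["day"].to_numpy(float), sub["H"].to_numpy(float))
    return float(fit.slope), float(fit.stderr)
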