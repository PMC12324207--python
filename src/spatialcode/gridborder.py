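"""Spatial autocorrelograms, grid scores, border scores, and
autocorrelogram principal components.

The spatial autocorrelogram is the lag-by-lag Pearson correlation of a rate
map with a shifted copy of itself, computed only over bin pairs where both
copies are valid.  The grid score quantifies six-fold rotational symmetry:
the annular region around the central peak is correlated with itself rotated
by 30/60/90/120/150 degrees and the score is
``min(r60, r120) - max(r30, r90, r150)``.  The border score
``b = (cM - dm) / (cM + dm)`` combines the maximum single-field wall
coverage cM with the rate-weighted mean distance of field bins from their
nearest wall, dm, normalized by half the arena side.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, signal

from .maps import FieldSet, RateMap

__all__ = [
    "Autocorrelogram",
    "GridScore",
    "BorderScore",
    "spatial_autocorrelation",
    "grid_score",
    "border_score",
    "ac_principal_components",
]

#: Lags supported by fewer overlapping valid bins are undefined.
MIN_OVERLAP_BINS = 20


@dataclass
class Autocorrelogram:
    """2D autocorrelation grid; NaN marks undefined lags."""

    r: np.ndarray  # (2n-1, 2n-1); r[n-1, n-1] is the zero lag
    n_overlap: np.ndarray

    @property
    def center(self) -> tuple[int, int]:
        return (self.r.shape[0] // 2, self.r.shape[1] // 2)


@dataclass
class GridScore:
    score: float  # NaN when undefined
    correlations_at: dict[int, float]
    annulus_inner: float = float("nan")
    annulus_outer: float = float("nan")

    @property
    def defined(self) -> bool:
        return np.isfinite(self.score)


@dataclass
class BorderScore:
    b: float  # NaN when no fields
    cM: float
    dm: float

    @property
    def defined(self) -> bool:
        return np.isfinite(self.b)


def _xcorr(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """c[tau] = sum_x u(x) v(x - tau), full lag range."""
    return signal.fftconvolve(u, v[::-1, ::-1], mode="full")


def spatial_autocorrelation(rmap: RateMap,
                            min_overlap: int = MIN_OVERLAP_BINS
                            ) -> Autocorrelogram:
    """Pearson autocorrelation of the rate map at every spatial lag.

    For each lag the correlation is computed over the overlapping valid-bin
    pairs using the standard product-moment form
    ``(n*Sxy - Sx*Sy) / sqrt((n*Sxx - Sx^2)(n*Syy - Sy^2))``; lags with
    fewer than ``min_overlap`` overlapping bins, or zero variance on either
    side, are NaN.
    """
    if int(rmap.valid.sum()) < MIN_OVERLAP_BINS:
        raise ValueError("rate map needs at least 20 valid bins")
    a = np.where(rmap.valid, rmap.rate, 0.0)
    m = rmap.valid.astype(float)
    a2 = a * a
    n_ov = _xcorr(m, m)
    sx = _xcorr(a, m)
    sy = _xcorr(m, a)
    sxy = _xcorr(a, a)
    sxx = _xcorr(a2, m)
    syy = _xcorr(m, a2)
    n_ov = np.round(n_ov)
    with np.errstate(invalid="ignore", divide="ignore"):
        num = n_ov * sxy - sx * sy
        var_x = n_ov * sxx - sx ** 2
        var_y = n_ov * syy - sy ** 2
        den = np.sqrt(np.maximum(var_x, 0.0) * np.maximum(var_y, 0.0))
        r = num / den
    eps = 1e-9 * np.maximum(n_ov, 1) ** 2
    bad = (n_ov < min_overlap) | (var_x <= eps) | (var_y <= eps)
    r[bad] = np.nan
    r = np.clip(r, -1.0, 1.0)
    return Autocorrelogram(r=r, n_overlap=n_ov.astype(int))


def _central_field(r: np.ndarray, center: tuple[int, int],
                   level: float = 0.2) -> np.ndarray:
    """Bins connected to the zero-lag peak with r above ``level``."""
    supra = np.isfinite(r) & (r > level)
    labeled, _ = ndimage.label(supra)
    lab = labeled[center]
    if lab == 0:
        out = np.zeros_like(supra)
        out[center] = True
        return out
    return labeled == lab


def _rotate_about_center(arr: np.ndarray, angle_deg: float) -> np.ndarray:
    return ndimage.rotate(arr, angle_deg, reshape=False, order=1,
                          mode="constant", cval=0.0)


def grid_score(ac: Autocorrelogram, annulus_expand: float = 1.25,
               central_level: float = 0.2) -> GridScore:
    """Six-fold symmetry score of the autocorrelogram.

    The central autocorrelation field (bins connected to the zero lag above
    ``central_level``) is excised; the annulus extends from its edge to
    ``annulus_expand`` times the mean distance of the six local maxima
    nearest the center.  The annulus is correlated with bilinear rotations
    of itself; the score is min(r60, r120) - max(r30, r90, r150).
    """
    r = ac.r
    cy, cx = ac.center
    yy, xx = np.indices(r.shape)
    dist = np.hypot(yy - cy, xx - cx)
    central = _central_field(r, (cy, cx), central_level)
    inner = float(dist[central].max()) + 1.0

    finite = np.isfinite(r)
    filled = np.where(finite, r, 0.0)
    local_max = (ndimage.maximum_filter(filled, size=3) == filled)
    peaks = local_max & finite & (r > 0) & ~central & (dist > inner)
    pr, pc = np.nonzero(peaks)
    if pr.size == 0:
        return GridScore(score=float("nan"), correlations_at={})
    pd = np.sort(np.hypot(pr - cy, pc - cx))
    outer = annulus_expand * float(pd[: min(6, pd.size)].mean())
    outer = min(outer, float(dist[finite].max()))
    if outer <= inner:
        return GridScore(score=float("nan"), correlations_at={},
                         annulus_inner=inner, annulus_outer=outer)

    annulus = finite & (dist > inner) & (dist <= outer)
    valid = finite.astype(float)
    corrs: dict[int, float] = {}
    for angle in (30, 60, 90, 120, 150):
        rot = _rotate_about_center(filled, angle)
        rot_valid = _rotate_about_center(valid, angle)
        sel = annulus & (rot_valid > 0.999)
        if sel.sum() < MIN_OVERLAP_BINS:
            return GridScore(score=float("nan"), correlations_at=corrs,
                             annulus_inner=inner, annulus_outer=outer)
        u, v = filled[sel], rot[sel]
        su, sv = u.std(), v.std()
        if su == 0 or sv == 0:
            corrs[angle] = 0.0
        else:
            corrs[angle] = float(np.corrcoef(u, v)[0, 1])
    score = (min(corrs[60], corrs[120])
             - max(corrs[30], corrs[90], corrs[150]))
    return GridScore(score=float(score), correlations_at=corrs,
                     annulus_inner=inner, annulus_outer=outer)


def border_score(rmap: RateMap, fields: FieldSet,
                 extent: float | None = None) -> BorderScore:
    """Border score b = (cM - dm) / (cM + dm).

    cM is the maximum, over fields and the four walls, of the fraction of
    bins in the wall-adjacent row/column occupied by a single field.  dm is
    the mean distance of field bins from their nearest wall — measured in
    whole bins, so wall-adjacent bins are at distance zero — weighted by the
    field rates normalized to a probability distribution, and divided by
    half the shortest arena side.
    """
    if fields.n_fields == 0:
        return BorderScore(b=float("nan"), cM=float("nan"), dm=float("nan"))
    extent = extent if extent is not None else rmap.extent
    n_rows, n_cols = rmap.rate.shape
    cM = 0.0
    for f in fields.fields:
        rows, cols = f[:, 0], f[:, 1]
        for cov in (np.sum(rows == 0) / n_cols,
                    np.sum(rows == n_rows - 1) / n_cols,
                    np.sum(cols == 0) / n_rows,
                    np.sum(cols == n_cols - 1) / n_rows):
            cM = max(cM, float(cov))
    all_bins = np.concatenate(fields.fields, axis=0)
    rows, cols = all_bins[:, 0], all_bins[:, 1]
    d_bins = np.minimum.reduce([rows, n_rows - 1 - rows,
                                cols, n_cols - 1 - cols])
    d_cm = d_bins * rmap.bin_size
    w = rmap.rate[rows, cols]
    wsum = w.sum()
    if wsum <= 0:
        w = np.ones_like(w)
        wsum = w.sum()
    dm = float(np.sum(w / wsum * d_cm) / (extent / 2.0))
    if cM + dm == 0:
        return BorderScore(b=float("nan"), cM=cM, dm=dm)
    return BorderScore(b=float((cM - dm) / (cM + dm)), cM=cM, dm=dm)


def ac_principal_components(acs: list[Autocorrelogram], k: int = 3,
                            target_shape: tuple[int, int] | None = None
                            ) -> tuple[np.ndarray, np.ndarray]:
    """First ``k`` principal-component scores of the flattened, mean-centered
    autocorrelograms across units.

    Autocorrelograms are resampled (bilinear) to a common shape; undefined
    lags are treated as zero correlation.  Returns ``(scores, explained)``
    with ``scores`` of shape (n_units, k).
    """
    from sklearn.decomposition import PCA

    if len(acs) < k + 1:
        raise ValueError(f"need at least {k + 1} units for {k} components")
    if target_shape is None:
        target_shape = min((ac.r.shape for ac in acs))
    mats = []
    for ac in acs:
        filled = np.where(np.isfinite(ac.r), ac.r, 0.0)
        if filled.shape != target_shape:
            zoom = (target_shape[0] / filled.shape[0],
                    target_shape[1] / filled.shape[1])
            filled = ndimage.zoom(filled, zoom, order=1)
            filled = filled[: target_shape[0], : target_shape[1]]
        mats.append(filled.ravel())
    X = np.asarray(mats)
    Xc = X - X.mean(axis=0)
    if not np.any(Xc):
        return np.zeros((len(acs), k)), np.zeros(k)
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(X)
    return scores, pca.explained_variance_ratio_
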