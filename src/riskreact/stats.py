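"""Second-level statistics for prioritization maps.

A per-subject map stack (subject x train bin x task bin) is related to a
behavioral covariate by robust (bisquare IRLS) linear regression at every
map cell; the covariate coefficient's t-statistic map is smoothed with a 2-D
Gaussian kernel and family-wise error over the map is controlled with a
max-statistic (or min-statistic) permutation test: the covariate-to-subject
assignment is permuted, the smoothed t-map recomputed, and the observed
extremum compared to the permutation distribution of extrema.

The IRLS is hand-vectorized over permutations and map cells so the
whole-null calibration (hundreds of replicates x hundreds of permutations)
runs in seconds; it is cross-checked against statsmodels' RLM in the test
suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy import stats as sps

__all__ = [
    "GroupStatResult",
    "robust_slope_t",
    "second_level_tmap",
    "smooth_map",
    "permutation_fwe",
    "spearman_onetailed",
    "spearman_t_from_r",
]

BISQUARE_C = 4.685
MIN_SUBJECTS = 5


@dataclass
class GroupStatResult:
    t_map: np.ndarray
    smoothed_map: np.ndarray
    peak_value: float
    peak_location: tuple
    null_extrema: np.ndarray
    p_fwe: float
    tail: str
    n_perm: int


def _bisquare_irls(x: np.ndarray, y: np.ndarray, max_iter: int = 30, tol: float = 1e-6):
    """Vectorized bisquare IRLS of y on [1, x] along the last axis.

    ``x`` and ``y`` broadcast against each other; the subject axis is last.
    Returns (slope, t) with shapes of the broadcast batch.  Scale is the
    median absolute residual / 0.6745, re-estimated each iteration; the
    slope's standard error comes from the converged weighted least squares,
    se^2 = [sum(w r^2) / (n - 2)] * [(X'WX)^{-1}]_slope.
    """
    x, y = np.broadcast_arrays(np.asarray(x, float), np.asarray(y, float))
    n = x.shape[-1]
    w = np.ones_like(y)
    b1 = np.zeros(x.shape[:-1])
    eps = 1e-12
    for _ in range(max_iter):
        sw = w.sum(-1)
        swx = (w * x).sum(-1)
        swy = (w * y).sum(-1)
        swxx = (w * x * x).sum(-1)
        swxy = (w * x * y).sum(-1)
        det = sw * swxx - swx**2
        det = np.where(np.abs(det) < eps, eps, det)
        b1_new = (sw * swxy - swx * swy) / det
        b0 = (swy - b1_new * swx) / np.where(sw < eps, eps, sw)
        r = y - b0[..., None] - b1_new[..., None] * x
        s = np.median(np.abs(r), axis=-1) / 0.6745
        s = np.maximum(s, eps + 1e-8 * np.median(np.abs(y), axis=-1))
        u = r / (BISQUARE_C * s[..., None])
        w = np.where(np.abs(u) < 1.0, (1.0 - u**2) ** 2, 0.0)
        # keep at least an OLS fallback if everything got zero weight
        dead = w.sum(-1) < eps
        if np.any(dead):
            w[dead] = 1.0
        delta = np.max(np.abs(b1_new - b1)) if b1_new.size else 0.0
        b1 = b1_new
        if delta < tol:
            break
    sigma2 = (w * r**2).sum(-1) / max(n - 2, 1)
    var_b1 = sigma2 * sw / det
    t = b1 / np.sqrt(np.maximum(var_b1, eps))
    return b1, t


def robust_slope_t(x: np.ndarray, y: np.ndarray):
    """Robust regression of y on x (1-D, subjects last); returns (slope, t)."""
    return _bisquare_irls(x, y)


def second_level_tmap(maps: np.ndarray, covariate: np.ndarray) -> np.ndarray:
    """Robust-regression t-map of per-subject maps on a covariate.

    ``maps`` is (n_subjects, *map_shape); cells undefined (NaN) for some
    subjects are fit on the remaining subjects when at least ``MIN_SUBJECTS``
    have data, otherwise propagated as NaN.
    """
    maps = np.asarray(maps, float)
    covariate = np.asarray(covariate, float)
    n_subj = maps.shape[0]
    if n_subj < MIN_SUBJECTS:
        raise ValueError(f"need at least {MIN_SUBJECTS} subjects")
    map_shape = maps.shape[1:]
    Y = maps.reshape(n_subj, -1).T  # (n_cells, n_subj)
    finite = np.isfinite(Y)
    t_flat = np.full(Y.shape[0], np.nan)
    complete = finite.all(axis=1)
    if complete.any():
        _, t_flat[complete] = _bisquare_irls(covariate[None, :], Y[complete])
    for c in np.flatnonzero(~complete):
        keep = finite[c]
        if keep.sum() >= MIN_SUBJECTS:
            _, t = _bisquare_irls(covariate[keep], Y[c, keep])
            t_flat[c] = t
    return t_flat.reshape(map_shape)


def smooth_map(map2d: np.ndarray, sigma: float = 1.5) -> np.ndarray:
    """2-D Gaussian smoothing (kernel truncated at 4 sigma).

    Undefined (NaN) cells are excluded and the kernel renormalized over the
    defined in-bounds neighbourhood; originally-NaN cells stay NaN.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    map2d = np.asarray(map2d, float)
    nan = ~np.isfinite(map2d)
    if not nan.any():
        num = ndimage.gaussian_filter(map2d, sigma, mode="constant", truncate=4.0)
        den = ndimage.gaussian_filter(
            np.ones_like(map2d), sigma, mode="constant", truncate=4.0
        )
        return num / den
    filled = np.where(nan, 0.0, map2d)
    weight = np.where(nan, 0.0, 1.0)
    num = ndimage.gaussian_filter(filled, sigma, mode="constant", truncate=4.0)
    den = ndimage.gaussian_filter(weight, sigma, mode="constant", truncate=4.0)
    out = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan)
    out[nan] = np.nan
    return out


def _smooth_stack(stack: np.ndarray, sigma: float) -> np.ndarray:
    """Smooth the trailing two axes of a (batch, h, w) stack (no NaNs)."""
    num = ndimage.gaussian_filter(stack, (0, sigma, sigma), mode="constant", truncate=4.0)
    den = ndimage.gaussian_filter(
        np.ones(stack.shape[1:]), sigma, mode="constant", truncate=4.0
    )
    return num / den[None]


def permutation_fwe(
    maps: np.ndarray,
    covariate: np.ndarray,
    n_perm: int = 5000,
    tail: str = "max",
    sigma: float = 1.5,
    seed: int = 0,
    chunk: int = 200,
) -> GroupStatResult:
    """Max/min-statistic permutation FWE test on a smoothed t-map.

    For each of ``n_perm`` seeded permutations of the covariate-to-subject
    assignment the smoothed robust t-map is recomputed and its extremum
    (max for ``tail="max"``, min for ``tail="min"``) recorded.  The
    family-wise p-value counts null extrema at least as extreme as the
    observed peak, with the identity assignment included:
    p = (1 + #extreme) / (n_perm + 1).  Cells undefined for any subject are
    excluded from both the observed and the permuted extrema.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    if tail not in ("max", "min"):
        raise ValueError("tail must be 'max' or 'min'")
    maps = np.asarray(maps, float)
    covariate = np.asarray(covariate, float)
    n_subj = maps.shape[0]
    map_shape = maps.shape[1:]
    rng = np.random.default_rng(seed)

    t_map = second_level_tmap(maps, covariate)
    smoothed = smooth_map(t_map, sigma)
    finite = np.isfinite(smoothed)
    if not finite.any():
        raise ValueError("no defined cells in the map")
    extremum = np.nanmax if tail == "max" else np.nanmin
    peak_value = float(extremum(smoothed))
    flat_peak = (
        np.nanargmax(smoothed) if tail == "max" else np.nanargmin(smoothed)
    )
    peak_location = tuple(int(v) for v in np.unravel_index(flat_peak, map_shape))

    # permutation null, batched over permutations x cells
    Y = maps.reshape(n_subj, -1).T  # (n_cells, n_subj)
    defined = np.isfinite(Y).all(axis=1)
    Yd = Y[defined]
    null_extrema = np.empty(n_perm)
    perms = np.array([rng.permutation(n_subj) for _ in range(n_perm)])
    for start in range(0, n_perm, chunk):
        xp = covariate[perms[start : start + chunk]]  # (m, n_subj)
        _, t = _bisquare_irls(xp[:, None, :], Yd[None, :, :])  # (m, n_cells_def)
        full = np.full((t.shape[0],) + (Y.shape[0],), np.nan)
        full[:, defined] = t
        stack = full.reshape((t.shape[0],) + map_shape)
        if np.isnan(stack).any():
            sm = np.stack([smooth_map(m2, sigma) for m2 in stack])
        else:
            sm = _smooth_stack(stack, sigma)
        ext = (
            np.nanmax(sm.reshape(sm.shape[0], -1), axis=1)
            if tail == "max"
            else np.nanmin(sm.reshape(sm.shape[0], -1), axis=1)
        )
        null_extrema[start : start + len(ext)] = ext

    if tail == "max":
        n_extreme = int(np.sum(null_extrema >= peak_value))
    else:
        n_extreme = int(np.sum(null_extrema <= peak_value))
    p_fwe = (1.0 + n_extreme) / (n_perm + 1.0)
    return GroupStatResult(
        t_map=t_map,
        smoothed_map=smoothed,
        peak_value=peak_value,
        peak_location=peak_location,
        null_extrema=null_extrema,
        p_fwe=float(p_fwe),
        tail=tail,
        n_perm=n_perm,
    )


def spearman_t_from_r(r: float, n: int) -> float:
    """t statistic of a (rank) correlation r at sample size n: r*sqrt(n-2)/sqrt(1-r^2)."""
    if not -1.0 < r < 1.0:
        raise ValueError("r must lie strictly inside (-1, 1)")
    if n < 3:
        raise ValueError("need n >= 3")
    return float(r * np.sqrt(n - 2) / np.sqrt(1.0 - r**2))


def spearman_onetailed(x, y, tail: str = "neg") -> tuple[float, float, float]:
    """One-tailed Spearman rank correlation via the t approximation.

    r is the Pearson correlation of (average) ranks; t = r sqrt(n-2) /
    sqrt(1-r^2) with n-2 degrees of freedom; p is the stated tail's
    probability under the t distribution.
    """
    if tail not in ("neg", "pos"):
        raise ValueError("tail must be 'neg' or 'pos'")
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("x and y must have equal length >= 3")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    if np.std(rx) == 0 or np.std(ry) == 0:
        raise ValueError("zero variance in ranks")
    r = float(np.corrcoef(rx, ry)[0, 1])
    n = len(x)
    if abs(r) >= 1.0:
        t = np.inf * np.sign(r)
    else:
        t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r**2)
    df = n - 2
    p = float(sps.t.cdf(t, df) if tail == "neg" else sps.t.sf(t, df))
    return r, float(t), p
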