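"""Background flattening and background-noise modelling for AFM height maps.

AFM topographs carry instrument background on top of the sample: overall tilt
of the mica substrate, scanner bow (a smooth quadratic warp along the fast
scan axis), and per-scan-line offsets from feedback drift.  The flattening
chain here removes these while protecting real topography:

1. subtract the global least-squares plane, then each row's median
   (:func:`plane_and_line_flatten`);
2. mask pixels that stand above the background by a robust threshold
   (:func:`make_feature_mask`) so fibrils do not bias the fit;
3. fit and subtract a second-order polynomial per scan line using only
   unmasked pixels (:func:`rowwise_poly_flatten`);
4. fit a Gaussian to the histogram of background pixel heights by
   Levenberg-Marquardt least squares; its peak defines the zero of the height
   scale, and its width the background noise level
   (:func:`fit_background_gaussian`).

:func:`flatten_pipeline` chains these, iterating mask -> flatten so that the
mask can be recomputed on the improved background.  Masking features before
the polynomial fit is what keeps bright fibrils from dragging the background
estimate up and carving artefactual troughs around them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from numpy.polynomial import polynomial as npoly
from scipy.optimize import curve_fit

from .io import HeightMap

#: Consistency factor turning a median absolute deviation into a normal sigma.
MAD_SCALE = 1.4826


class FlattenError(ValueError):
    """Raised when an image cannot be flattened (degenerate shape or mask)."""


class DegenerateBackgroundError(FlattenError):
    """Raised when the background height distribution has zero spread."""


@dataclass
class BackgroundModel:
    """Fitted background description for one image.

    ``plane_coeffs`` are (offset nm, x-slope nm/px, y-slope nm/px) of the
    global plane.  ``row_poly_coeffs`` holds one row of polynomial
    coefficients per scan line, in ascending powers of the scaled column
    coordinate x' = (col - c)/c with c = (n_cols - 1)/2 (scaling keeps the
    normal equations well conditioned at 1024 px).  ``mu`` and ``sigma`` are
    the centre and width of the Gaussian fitted to the background pixel-height
    histogram; after :func:`flatten_pipeline` all heights are relative to
    ``mu``, so downstream thresholds are multiples of ``sigma`` alone.
    """

    plane_coeffs: np.ndarray
    row_poly_coeffs: np.ndarray
    mu: float
    sigma: float
    fit_converged: bool = True

    def to_dict(self) -> dict:
        return {
            "plane_coeffs": np.asarray(self.plane_coeffs).tolist(),
            "row_poly_coeffs": np.asarray(self.row_poly_coeffs).tolist(),
            "mu": float(self.mu),
            "sigma": float(self.sigma),
            "fit_converged": bool(self.fit_converged),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BackgroundModel":
        return cls(
            plane_coeffs=np.asarray(d["plane_coeffs"], dtype=float),
            row_poly_coeffs=np.asarray(d["row_poly_coeffs"], dtype=float),
            mu=float(d["mu"]),
            sigma=float(d["sigma"]),
            fit_converged=bool(d.get("fit_converged", True)),
        )


def _scaled_x(n_cols: int) -> np.ndarray:
    c = (n_cols - 1) / 2.0
    if c == 0:
        return np.zeros(1)
    return (np.arange(n_cols) - c) / c


def plane_and_line_flatten(hmap: HeightMap) -> HeightMap:
    """Subtract the least-squares best-fit plane, then each row's median."""
    z = hmap.heights
    ny, nx = z.shape
    if ny < 2 or nx < 2:
        raise FlattenError(
            f"image of shape {z.shape} is degenerate; need at least 2 x 2 pixels"
        )
    yy, xx = np.mgrid[0:ny, 0:nx]
    A = np.column_stack([np.ones(z.size), xx.ravel(), yy.ravel()])
    coeffs, *_ = np.linalg.lstsq(A, z.ravel(), rcond=None)
    flat = z - (A @ coeffs).reshape(z.shape)
    flat = flat - np.median(flat, axis=1, keepdims=True)
    return hmap.with_heights(flat)


def make_feature_mask(hmap: HeightMap, k: float = 3.0) -> np.ndarray:
    """Boolean mask of pixels standing above the background.

    A pixel is masked (True) when its height exceeds
    ``median + k * 1.4826 * MAD`` of the whole image — a robust surrogate for
    the by-eye threshold an operator would choose, insensitive to the features
    themselves as long as they cover a minority of the image.
    """
    if k <= 0:
        raise ValueError("k must be > 0")
    z = hmap.heights
    med = np.median(z)
    spread = MAD_SCALE * np.median(np.abs(z - med))
    mask = z > med + k * spread
    frac = mask.mean()
    if frac > 0.9:
        raise FlattenError(
            f"feature mask covers {100 * frac:.1f}% of pixels; threshold too "
            "low or image unusable for background fitting"
        )
    return mask


def rowwise_poly_flatten(
    hmap: HeightMap, mask: np.ndarray, order: int = 2
) -> tuple[HeightMap, np.ndarray]:
    """Fit and subtract a per-scan-line polynomial using unmasked pixels only.

    Each row's polynomial (default order 2, capturing line offset, residual
    tilt and bow) is least-squares fitted to the background pixels of that row
    and subtracted from the entire row, so heights of masked features are
    preserved relative to their local background.  Rows with fewer than
    ``order + 2`` background pixels (e.g. crossed end-to-end by a fibril)
    reuse the element-wise median of the well-fitted rows' coefficients
    instead of destroying the row with an unconstrained fit.

    Returns the flattened map and the (n_rows, order + 1) coefficient matrix
    in the scaled column basis (see :class:`BackgroundModel`).
    """
    if order < 0:
        raise ValueError("order must be >= 0")
    z = hmap.heights
    if mask.shape != z.shape:
        raise FlattenError(
            f"mask shape {mask.shape} does not match image shape {z.shape}"
        )
    if mask.mean() > 0.9:
        raise FlattenError(
            "mask covers more than 90% of pixels; at least 10% must remain "
            "background for the polynomial fit"
        )
    ny, nx = z.shape
    x = _scaled_x(nx)
    coeffs = np.full((ny, order + 1), np.nan)
    min_pts = order + 2
    for i in range(ny):
        good = ~mask[i]
        if good.sum() >= min_pts:
            coeffs[i] = npoly.polyfit(x[good], z[i, good], order)
    bad = np.isnan(coeffs[:, 0])
    if bad.all():
        raise FlattenError("no row has enough unmasked pixels for a polynomial fit")
    if bad.any():
        coeffs[bad] = np.median(coeffs[~bad], axis=0)
    background = npoly.polyval(x, coeffs.T)  # (ny, nx)
    return hmap.with_heights(z - background), coeffs


def _gauss(h, A, mu, sigma):
    return A * np.exp(-((h - mu) ** 2) / (2.0 * sigma**2))


def fit_background_gaussian(
    hmap: HeightMap, mask: np.ndarray, n_bins: int = 256
) -> tuple[float, float, bool]:
    """Fit a Gaussian to the histogram of background (unmasked) pixel heights.

    The histogram spans the 0.1–99.9 percentile range of the background
    pixels in ``n_bins`` bins; ``A * exp(-(h - mu)^2 / 2 sigma^2)`` is fitted
    by Levenberg-Marquardt nonlinear least squares starting from the sample
    moments.  The fitted peak ``mu`` is the average background level, against
    which all feature heights are subsequently measured — far more stable than
    reading local height differences off a noisy background.

    Returns ``(mu, sigma, converged)``.  If the optimiser fails, the sample
    median and MAD-based sigma are returned with ``converged=False`` and a
    warning.
    """
    vals = hmap.heights[~np.asarray(mask, dtype=bool)]
    if vals.size < 1000:
        raise FlattenError(
            f"only {vals.size} background pixels; need >= 1000 for a stable fit"
        )
    lo, hi = np.percentile(vals, [0.1, 99.9])
    if not hi > lo:
        raise DegenerateBackgroundError(
            "background height distribution has zero spread (constant image?)"
        )
    counts, edges = np.histogram(vals, bins=n_bins, range=(lo, hi))
    centers = 0.5 * (edges[:-1] + edges[1:])
    mu0 = float(vals.mean())
    sigma0 = float(vals.std()) or (hi - lo) / 6.0
    A0 = float(counts.max())
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(
                _gauss,
                centers,
                counts,
                p0=(A0, mu0, sigma0),
                method="lm",
                maxfev=2000,
            )
        mu, sigma = float(popt[1]), float(abs(popt[2]))
        if not (np.isfinite(mu) and np.isfinite(sigma) and sigma > 0):
            raise RuntimeError("non-finite Gaussian parameters")
        return mu, sigma, True
    except (RuntimeError, TypeError) as exc:
        warnings.warn(
            f"Gaussian background fit failed ({exc}); falling back to "
            "median/MAD estimates",
            stacklevel=2,
        )
        med = float(np.median(vals))
        sig = float(MAD_SCALE * np.median(np.abs(vals - med))) or float(vals.std())
        return med, sig, False


def flatten_pipeline(
    hmap: HeightMap,
    mask_k: float = 3.0,
    n_passes: int = 2,
    poly_order: int = 2,
    n_bins: int = 256,
) -> tuple[HeightMap, BackgroundModel]:
    """Full flattening chain: plane/line flatten, iterated mask -> row-wise
    polynomial subtraction, then Gaussian background centring.

    ``n_passes`` controls how many mask -> flatten rounds run (default 2: the
    second pass recomputes the mask on the improved background, which
    stabilises it when the initial tilt or bow is large).  The returned map
    has its background centred at zero (``mu`` subtracted); the model records
    the plane, the final pass's per-row polynomial coefficients and the
    Gaussian ``(mu, sigma)``.

    A perfectly flat (constant or noise-free) image short-circuits the
    Gaussian fit: ``sigma`` is set to 0 with ``fit_converged=False``, and the
    map is returned as-is.
    """
    if n_passes < 1:
        raise ValueError("n_passes must be >= 1")
    z = hmap.heights
    ny, nx = z.shape
    yy, xx = np.mgrid[0:ny, 0:nx]
    A = np.column_stack([np.ones(z.size), xx.ravel(), yy.ravel()])
    plane_coeffs, *_ = np.linalg.lstsq(A, z.ravel(), rcond=None)

    flat = plane_and_line_flatten(hmap)
    row_coeffs = np.zeros((ny, poly_order + 1))
    for _ in range(n_passes):
        mask = make_feature_mask(flat, mask_k)
        flat, row_coeffs = rowwise_poly_flatten(flat, mask, poly_order)
    mask = make_feature_mask(flat, mask_k)
    try:
        mu, sigma, converged = fit_background_gaussian(flat, mask, n_bins)
    except DegenerateBackgroundError:
        vals = flat.heights[~mask]
        mu = float(np.median(vals))
        sigma = 0.0
        converged = False
        warnings.warn(
            "background distribution degenerate; sigma set to 0", stacklevel=2
        )
    centred = flat.with_heights(flat.heights - mu)
    model = BackgroundModel(
        plane_coeffs=plane_coeffs,
        row_poly_coeffs=row_coeffs,
        mu=mu,
        sigma=sigma,
        fit_converged=converged,
    )
    return centred, model
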