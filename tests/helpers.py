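"""Independent brute-force oracles used to validate the implementation.

Everything here is deliberately naive: exhaustive pixel enumeration for
geometry, explicit sum-of-squares loops for the ANOVA decomposition.  The
oracles share no code path with the package.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import cdist


def bruteforce_distance_to_mask(mask: np.ndarray) -> np.ndarray:
    """Euclidean distance (px) from every pixel center to the nearest mask
    pixel center, by exhaustive pairwise distances."""
    mask = np.asarray(mask, dtype=bool)
    rows, cols = mask.shape
    yy, xx = np.mgrid[0:rows, 0:cols]
    all_pts = np.stack([yy.ravel(), xx.ravel()], axis=1).astype(float)
    mask_pts = np.argwhere(mask).astype(float)
    d = cdist(all_pts, mask_pts).min(axis=1)
    return d.reshape(rows, cols)


def bruteforce_dilate(mask: np.ndarray, radius_px: float) -> np.ndarray:
    """Dilation by exhaustive distance thresholding (<= radius)."""
    return bruteforce_distance_to_mask(mask) <= radius_px


def bruteforce_disk_area(center: tuple[float, float], radius: float, shape) -> int:
    """Number of pixel centers strictly within ``radius`` of ``center``."""
    cy, cx = center
    rows, cols = shape
    count = 0
    for r in range(rows):
        for c in range(cols):
            if (r - cy) ** 2 + (c - cx) ** 2 < radius**2:
                count += 1
    return count


def anova_icc_a_k(x: np.ndarray) -> float:
    """ICC(A,k) from an explicitly looped two-way ANOVA decomposition."""
    x = np.asarray(x, dtype=float)
    n, k = x.shape
    grand = x.sum() / (n * k)
    ss_rows = 0.0
    for i in range(n):
        ss_rows += (x[i].sum() / k - grand) ** 2
    msr = k * ss_rows / (n - 1)
    ss_cols = 0.0
    for j in range(k):
        ss_cols += (x[:, j].sum() / n - grand) ** 2
    msc = n * ss_cols / (k - 1)
    sse = 0.0
    for i in range(n):
        for j in range(k):
            sse += (x[i, j] - x[i].sum() / k - x[:, j].sum() / n + grand) ** 2
    mse = sse / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (msc - mse) / n)


def simulate_rater_matrix(
    n: int, k: int, subject_sd: float, rater_sd: float, residual_sd: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Additive two-way model: x_ij = s_i + r_j + e_ij."""
    s = rng.normal(0.0, subject_sd, size=n)[:, None]
    r = rng.normal(0.0, rater_sd, size=k)[None, :]
    e = rng.normal(0.0, residual_sd, size=(n, k))
    return s + r + e


def analytic_icc_a_k(subject_sd: float, rater_sd: float, residual_sd: float, k: int) -> float:
    """Variance-component ICC for the mean of k raters under the additive
    model: sigma_s^2 / (sigma_s^2 + (sigma_r^2 + sigma_e^2) / k)."""
    vs, vr, ve = subject_sd**2, rater_sd**2, residual_sd**2
    return vs / (vs + (vr + ve) / k)
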