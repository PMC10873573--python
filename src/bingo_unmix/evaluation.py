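"""Quantitative evaluation of unmixing runs.

NMF output is defined only up to a permutation and per-component scale, so
every ground-truth comparison first solves an optimal assignment between
estimated components and references (by spectral angle when reference
spectra are available, by image correlation otherwise) and normalizes the
per-component scale away. The metrics themselves are the field's standard
ones: pairwise 2-D correlation (crosstalk heatmaps), SSIM, Dice on
Otsu-binarized masks, reconstruction RMSE, and spectral angle distance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.optimize

from .imagestack import ImageMatrix
from .solver import FactorizationResult
from .synthetic import MixingMatrix, Phantom

__all__ = [
    "MetricsReport",
    "corr2d",
    "crosstalk_heatmap",
    "ssim",
    "dice",
    "rmse",
    "sad",
    "match_components",
    "evaluate",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MetricsReport:
    """Per-component and averaged scores of one unmixing run.

    ``matching[i]`` is the index of the estimated component assigned to
    reference/truth i; all per-component arrays follow reference order.
    SAD entries are NaN when no reference spectra were supplied.
    """

    ssim_per_component: np.ndarray
    dice_per_component: np.ndarray
    sad_per_component: np.ndarray  # radians
    ssim_mean: float
    dice_mean: float
    rmse: float
    heatmap: np.ndarray
    matching: tuple[int, ...]

    @property
    def sad_degrees(self) -> np.ndarray:
        return np.degrees(self.sad_per_component)


def corr2d(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation of the flattened pixel values of two same-sized
    images; undefined (error) when either image is constant."""
    a = np.asarray(a, dtype=np.float64).ravel()
    b = np.asarray(b, dtype=np.float64).ravel()
    if a.size != b.size:
        raise ValueError("images must have the same size")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("zero variance: 2-D correlation undefined for constant images")
    return float(np.corrcoef(a, b)[0, 1])


def crosstalk_heatmap(
    images: list[np.ndarray], others: list[np.ndarray] | None = None
) -> np.ndarray:
    """Matrix of pairwise 2-D correlations.

    With one list: symmetric with exact unit diagonal (crosstalk within a
    set of channel or component images). With two lists: the rectangular
    cross-correlation matrix (e.g. unmixed vs truth).
    """
    if others is None:
        k = len(images)
        if k < 2:
            raise ValueError("need at least two images")
        M = np.eye(k)
        for i in range(k):
            for j in range(i + 1, k):
                M[i, j] = M[j, i] = corr2d(images[i], images[j])
        return M
    M = np.zeros((len(images), len(others)))
    for i, a in enumerate(images):
        for j, b in enumerate(others):
            M[i, j] = corr2d(a, b)
    return M


def ssim(a: np.ndarray, b: np.ndarray) -> float:
    """Structural similarity of two same-sized images.

    The pair is jointly rescaled to [0, 1] by its common maximum, then
    scored with the standard settings: 11x11 Gaussian window (sigma 1.5),
    K1=0.01, K2=0.03, dynamic range 1. Images smaller than the window fall
    back to a single global window (logged).
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("images must have the same size")
    peak = max(a.max(), b.max())
    if peak > 0:
        a = a / peak
        b = b / peak
    c1, c2 = 0.01**2, 0.03**2
    if min(a.shape) < 11:
        logger.info("ssim: image smaller than the 11x11 window, using global SSIM")
        mu_a, mu_b = a.mean(), b.mean()
        va, vb = a.var(), b.var()
        cov = ((a - mu_a) * (b - mu_b)).mean()
        return float(
            (2 * mu_a * mu_b + c1)
            * (2 * cov + c2)
            / ((mu_a**2 + mu_b**2 + c1) * (va + vb + c2))
        )
    from skimage.metrics import structural_similarity

    return float(
        structural_similarity(
            a,
            b,
            win_size=11,
            gaussian_weights=True,
            sigma=1.5,
            K1=0.01,
            K2=0.03,
            use_sample_covariance=False,
            data_range=1.0,
        )
    )


def _binarize(im: np.ndarray) -> np.ndarray:
    im = np.asarray(im, dtype=np.float64)
    if np.ptp(im) == 0:
        return im > 0  # constant image: empty mask if zero, full if positive
    from skimage.filters import threshold_otsu

    return im > threshold_otsu(im)


def dice(a: np.ndarray, b: np.ndarray, threshold: float | None = None) -> float:
    """Dice coefficient of the two images' foreground masks.

    Masks come from a per-image Otsu threshold (parameter-free and
    deterministic) unless a fixed threshold is supplied; two empty masks
    count as perfect agreement (1).
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("images must have the same size")
    if threshold is None:
        ma, mb = _binarize(a), _binarize(b)
    else:
        ma, mb = a > threshold, b > threshold
    total = int(ma.sum()) + int(mb.sum())
    if total == 0:
        return 1.0
    return float(2.0 * np.logical_and(ma, mb).sum() / total)


def rmse(X: ImageMatrix | np.ndarray, W: np.ndarray, H: np.ndarray) -> float:
    """Root mean square reconstruction error sqrt(mean((X - WH)^2)) over all
    m*n entries, on the same normalization as the solver input."""
    X = X.values if isinstance(X, ImageMatrix) else np.asarray(X, dtype=np.float64)
    if X.shape != (W.shape[0], H.shape[1]) or W.shape[1] != H.shape[0]:
        raise ValueError("shape mismatch between X, W, H")
    return float(np.sqrt(np.mean((X - W @ H) ** 2)))


def sad(h: np.ndarray, s: np.ndarray) -> float:
    """Spectral angle distance (radians) between two spectra: arccos of
    their cosine similarity. Scale-invariant; 0 for identical directions,
    pi/2 for orthogonal nonnegative spectra."""
    h = np.asarray(h, dtype=np.float64).ravel()
    s = np.asarray(s, dtype=np.float64).ravel()
    nh, ns = np.linalg.norm(h), np.linalg.norm(s)
    if nh == 0 or ns == 0:
        raise ValueError("spectral angle of a zero vector is undefined")
    return float(np.arccos(np.clip(h @ s / (nh * ns), -1.0, 1.0)))


def match_components(
    H_est: np.ndarray,
    reference: MixingMatrix | np.ndarray,
    est_images: list[np.ndarray] | None = None,
    truth_images: np.ndarray | None = None,
) -> tuple[int, ...]:
    """Permutation resolving NMF's component-order ambiguity.

    With reference spectra: minimizes total spectral angle. With truth
    images (pass ``est_images``/``truth_images`` and ``reference=None``):
    maximizes total image correlation. Solved exactly by the Hungarian
    assignment; ties resolve deterministically. Returns ``perm`` with
    ``perm[i]`` = estimated index matched to reference i.
    """
    if reference is not None:
        ref = (
            reference.values
            if isinstance(reference, MixingMatrix)
            else np.asarray(reference, dtype=np.float64)
        )
        H_est = np.asarray(H_est, dtype=np.float64)
        if H_est.shape[0] != ref.shape[0]:
            raise ValueError("component counts differ")
        cost = np.array([[sad(ref[i], H_est[j]) for j in range(ref.shape[0])]
                         for i in range(ref.shape[0])])
    else:
        if est_images is None or truth_images is None:
            raise ValueError("need either reference spectra or image pairs")
        if len(est_images) != len(truth_images):
            raise ValueError("component counts differ")
        k = len(est_images)
        cost = np.zeros((k, k))
        for i in range(k):
            for j in range(k):
                try:
                    cost[i, j] = -corr2d(truth_images[i], est_images[j])
                except ValueError:
                    cost[i, j] = 0.0
    rows, cols = scipy.optimize.linear_sum_assignment(cost)
    perm = np.empty(len(rows), dtype=int)
    perm[rows] = cols
    return tuple(int(p) for p in perm)


def evaluate(
    result: FactorizationResult,
    phantom: Phantom,
    S: MixingMatrix | np.ndarray | None = None,
) -> MetricsReport:
    """Score an unmixing run against ground truth.

    Components are matched to the truths (by spectral angle against the
    reference mixing matrix when given, else by image correlation), then
    each matched image and truth is normalized to unit peak — abundances
    are defined only up to scale — before SSIM and Dice. The heatmap is the
    pairwise 2-D correlation of the matched unmixed images; RMSE is the
    reconstruction error on the solver's own input matrix.
    """
    if phantom.r != result.r:
        raise ValueError("component counts differ")
    est_images = result.images()
    if S is not None:
        perm = match_components(result.H, S)
        Smat = S.values if isinstance(S, MixingMatrix) else np.asarray(S)
    else:
        perm = match_components(
            result.H,
            None,
            est_images=est_images,
            truth_images=phantom.truths,
        )
        Smat = None
    r = result.r
    ssim_pc = np.zeros(r)
    dice_pc = np.zeros(r)
    sad_pc = np.full(r, np.nan)
    matched = []
    for i in range(r):
        est = est_images[perm[i]]
        truth = phantom.truths[i]
        est_n = est / est.max() if est.max() > 0 else est
        truth_n = truth / truth.max() if truth.max() > 0 else truth
        ssim_pc[i] = ssim(est_n, truth_n)
        dice_pc[i] = dice(est_n, truth_n)
        if Smat is not None:
            sad_pc[i] = sad(result.H[perm[i]], Smat[i])
        matched.append(est)
    return MetricsReport(
        ssim_per_component=ssim_pc,
        dice_per_component=dice_pc,
        sad_per_component=sad_pc,
        ssim_mean=float(ssim_pc.mean()),
        dice_mean=float(dice_pc.mean()),
        rmse=rmse(result.X, result.W, result.H),
        heatmap=crosstalk_heatmap(matched) if r >= 2 else np.ones((1, 1)),
        matching=perm,
    )
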