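"""Blind unmixing by sparsity-constrained NMF (the BINGO factorization).

The multichannel image matrix ``X (m x n)`` is factorized as ``X ~= W H``
with ``W (m x r)`` the per-pixel fluorophore abundances and ``H (r x n)``
the per-fluorophore channel spectra, minimizing

    f(W, H) = ||X - W H||_F^2 + alpha * J1(H)

where J1 penalizes deviation of each spectrum row's Hoyer sparseness from a
target ``sp_h``. The workhorse of the method is the sparseness *projection*
rather than the soft penalty: during an initial constraint phase every H
row is projected onto sparseness exactly ``sp_h`` after each gradient step,
which collapses the scale/rotation continuum of near-exact factorizations
that plain NMF cannot resolve; a release phase then lets the fidelity term
polish the solution inside the selected basin, with the projection demoted
to a one-sided floor. Initialization is deterministic NNDSVD, the H update
is projected gradient descent with a backtracking line search, and W
follows the Lee-Seung multiplicative rule, so the whole pipeline has no
random state: two runs with the same inputs are bit-identical.

A reference-spectrum linear-unmixing baseline (per-pixel NNLS) and a
random-init no-penalty NMF comparator are provided for benchmarking.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.optimize

from .imagestack import ImageMatrix, ImageStack, flatten, unflatten
from .nndsvd import nndsvd
from .synthetic import MixingMatrix

__all__ = [
    "SolverConfig",
    "FactorizationResult",
    "row_sparseness",
    "matrix_sparseness",
    "sparseness_to_l1",
    "hoyer_project",
    "estimate_sp_h",
    "suggest_sp_h",
    "objective",
    "update_H",
    "update_W",
    "bingo_unmix",
    "subtract_crosstalk",
    "lu_baseline",
    "random_nmf",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SolverConfig:
    """Tunables of the factorization.

    sp_h
        Target sparseness of each spectrum row, in [0, 1]. Guidance: set it
        somewhat below the sparseness of the (expected) reference spectra —
        a target *above* the true spectral sparseness forces spurious
        structure, while a moderately lower target still collapses the
        crosstalk ambiguity and costs nothing after the release phase.
        ``None`` (default) estimates the target from the data itself as the
        median Hoyer sparseness of the nonzero pixel spectra minus
        ``sp_margin`` — in highly multiplexed images most pixels are
        dominated by few fluorophores, so pixel spectra are a serviceable
        blind proxy for the unknown reference spectra.
    sp_margin
        Safety margin subtracted by the blind estimate above.
    constraint_iter
        Iterations of the constraint phase, during which every H row is
        held at sparseness exactly sp_h by two-sided Hoyer projection.
        Afterwards the projection acts only as a floor (when
        ``enforce_floor``).
    alpha, anneal_iter, anneal_decay
        Weight of the soft sparsity penalty J1 in the objective, whose
        (sub)gradient pushes row sparseness down toward sp_h while the
        floor holds it up — the pairing that lets the iterate drift across
        the continuum of near-exact factorizations toward the least-sparse
        (crosstalk-free) one. ``None`` resolves to ``0.5 * m`` pixels,
        matching the scale of the squared-Frobenius fidelity of a
        max-normalized image. The weight stays constant through the
        constraint phase and for ``anneal_iter`` further iterations, then
        decays geometrically by ``anneal_decay`` so the fidelity term can
        polish the solution without penalty-induced bias; convergence is
        only monitored once the weight has decayed below 1e-4 of its
        initial value. Because the weight never increases and the floored
        penalty is clamped nonnegative, the recorded objective trace is
        monotone by construction.
    line_search
        (initial step multiplier on 1/L, shrink factor, max halvings) for
        the backtracking projected-gradient step; L is the Lipschitz
        constant 2*||W^T W||_2 of the fidelity gradient.
    rescue
        Deterministic repair of split/merge basins: when two estimated
        spectra end up far closer than physically distinct fluorophores
        ever are (spectral angle below ``rescue_sad``), one of the twins is
        dropped, the survivors briefly refit, the freed component is
        reseeded from the leading nonnegative direction of the unexplained
        residual, and the schedule reruns; the candidate with the lowest
        final objective wins. At most ``rescue_max`` rounds.
    """

    sp_h: float | None = None
    sp_margin: float = 0.2
    alpha: float | None = None
    max_iter: int = 1600
    constraint_iter: int = 400
    anneal_iter: int = 800
    anneal_decay: float = 0.95
    rel_tol: float = 1e-8
    line_search: tuple[float, float, int] = (1.0, 0.5, 30)
    normalize_input: bool = True
    zero_fill: float | str = 0.0
    penalty_form: str = "linear"
    enforce_floor: bool = True
    rescue: bool = True
    rescue_max: int = 4
    rescue_sad: float = 0.35

    def __post_init__(self) -> None:
        if self.sp_h is not None and not 0.0 <= self.sp_h <= 1.0:
            raise ValueError("sp_h must lie in [0, 1]")
        if self.alpha is not None and self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.constraint_iter < 0 or self.anneal_iter < 0:
            raise ValueError("phase lengths must be >= 0")
        if not 0.0 < self.anneal_decay <= 1.0:
            raise ValueError("anneal_decay must lie in (0, 1]")
        if self.penalty_form not in ("linear", "squared"):
            raise ValueError("penalty_form must be 'linear' or 'squared'")

    def resolved_alpha(self, m: int) -> float:
        """Initial penalty weight: explicit value, or 0.5 per pixel."""
        return 0.5 * m if self.alpha is None else float(self.alpha)


@dataclass(frozen=True)
class FactorizationResult:
    """Output of one unmixing run.

    ``W`` columns rearrange into the unmixed images (`images()`); ``H`` rows
    are the estimated spectra, each max-normalized to 1 with the
    compensating scale folded into W. Components are ordered by ascending
    peak-channel index (ties by descending total abundance) so output order
    is reproducible. ``X`` is the matrix the solver actually factorized
    (after optional max-normalization), kept for reconstruction-error
    reporting; ``sp_h`` is the resolved sparseness target of the run.
    """

    W: np.ndarray
    H: np.ndarray
    X: np.ndarray
    height: int
    width: int
    objective_trace: np.ndarray
    iterations: int
    converged: bool
    component_order: tuple[int, ...]
    sp_h: float

    @property
    def r(self) -> int:
        return self.H.shape[0]

    def images(self) -> list[np.ndarray]:
        return unflatten(self.W, self.height, self.width)


# ---------------------------------------------------------------------------
# sparseness measure and projection

def row_sparseness(v: np.ndarray) -> float:
    """Hoyer sparseness (sqrt(n) - L1/L2) / (sqrt(n) - 1) of a nonnegative
    vector: 1 for one-hot, 0 for constant, scale-invariant."""
    v = np.asarray(v, dtype=np.float64)
    n = v.size
    if n < 2:
        raise ValueError("sparseness needs at least 2 entries")
    l2 = np.linalg.norm(v)
    if l2 == 0:
        raise ValueError("sparseness of the zero vector is undefined")
    l1 = np.abs(v).sum()
    return float((np.sqrt(n) - l1 / l2) / (np.sqrt(n) - 1.0))


def matrix_sparseness(H: np.ndarray) -> float:
    """Mean Hoyer sparseness over the rows (per-fluorophore spectra)."""
    return float(np.mean([row_sparseness(row) for row in np.asarray(H)]))


def sparseness_to_l1(sp: float, l2: float, n: int) -> float:
    """L1 norm a length-n vector of Euclidean norm l2 must have to attain
    Hoyer sparseness ``sp``."""
    return l2 * (np.sqrt(n) - sp * (np.sqrt(n) - 1.0))


def hoyer_project(
    v: np.ndarray, l1_target: float, l2_target: float
) -> np.ndarray:
    """Closest nonnegative vector to ``v`` with the requested L1 and L2
    norms, by the standard alternating hyperplane/sphere projection with
    zeroing of negative entries."""
    v = np.asarray(v, dtype=np.float64)
    n = v.size
    if l2_target <= 0 or not (
        l2_target <= l1_target * (1 + 1e-12)
        and l1_target <= np.sqrt(n) * l2_target * (1 + 1e-12)
    ):
        raise ValueError(
            f"infeasible targets: need 0 < L2 <= L1 <= sqrt(n)*L2, got "
            f"L1={l1_target}, L2={l2_target}, n={n}"
        )
    s = v + (l1_target - v.sum()) / n
    zeroed = np.zeros(n, dtype=bool)
    for _ in range(n + 1):
        live = ~zeroed
        k = int(live.sum())
        mid = np.where(live, l1_target / k, 0.0)
        w = s - mid
        ww = float(w @ w)
        if ww < 1e-300:
            s = mid.copy()
        else:
            mw = float(mid @ w)
            mm = float(mid @ mid)
            disc = max(mw * mw - ww * (mm - l2_target**2), 0.0)
            a = (-mw + np.sqrt(disc)) / ww
            s = mid + a * w
        if np.all(s >= -1e-12 * l2_target):
            break
        neg = s < 0
        zeroed |= neg
        s[zeroed] = 0.0
        live = ~zeroed
        k = int(live.sum())
        if k == 0:
            break
        s[live] -= (s.sum() - l1_target) / k
    return np.clip(s, 0.0, None)


def _project_rows(H: np.ndarray, sp_h: float, exact: bool) -> np.ndarray:
    """Per-row sparseness projection at unchanged L2.

    ``exact``: every nonzero row is moved onto sparseness exactly sp_h
    (constraint phase). Otherwise only rows *below* sp_h are lifted onto it
    (floor). Zero rows pass through."""
    out = H.copy()
    n = H.shape[1]
    for i, row in enumerate(H):
        l2 = np.linalg.norm(row)
        if l2 == 0:
            continue
        sp = row_sparseness(row)
        if (exact and abs(sp - sp_h) > 1e-9) or (not exact and sp < sp_h - 1e-9):
            out[i] = hoyer_project(row, sparseness_to_l1(sp_h, l2, n), l2)
    return out


def estimate_sp_h(X: np.ndarray, margin: float = 0.2) -> float:
    """Blind sparseness target: median Hoyer sparseness of the nonzero
    pixel spectra, minus a safety margin.

    In highly multiplexed images most pixels carry one dominant fluorophore,
    so the typical pixel spectrum has roughly the sparseness of a reference
    spectrum; staying below it by a margin keeps the true spectra reachable
    from the constrained set."""
    X = X.values if isinstance(X, ImageMatrix) else np.asarray(X, dtype=np.float64)
    rows = X[X.any(axis=1)]
    if rows.size == 0:
        raise ValueError("cannot estimate a sparseness target from an all-zero matrix")
    med = float(np.median([row_sparseness(v) for v in rows]))
    return min(1.0, max(0.0, med - margin))


def suggest_sp_h(S: MixingMatrix | np.ndarray, margin: float = 0.05) -> float:
    """Recommended sparseness target given reference spectra: slightly below
    the mean row sparseness of the mixing matrix."""
    Smat = S.values if isinstance(S, MixingMatrix) else np.asarray(S)
    return max(0.0, matrix_sparseness(Smat) - margin)


# ---------------------------------------------------------------------------
# objective and updates

def _resolve_sp(config: SolverConfig, sp_h: float | None) -> float:
    if sp_h is not None:
        return sp_h
    if config.sp_h is not None:
        return config.sp_h
    raise ValueError("sp_h unresolved: set config.sp_h or pass sp_h explicitly")


def _penalty(
    H: np.ndarray, config: SolverConfig, sp_h: float, alpha: float
) -> float:
    if alpha == 0:
        return 0.0
    devs = np.array(
        [row_sparseness(row) - sp_h if np.any(row) else 0.0 for row in H]
    )
    j1 = float(devs.sum()) if config.penalty_form == "linear" else float(
        (devs**2).sum()
    )
    if config.enforce_floor:
        # the floor keeps every row at/above sp_h, so J1 >= 0 up to the
        # projection tolerance; clip the numerical residue
        j1 = max(j1, 0.0)
    return alpha * j1


def objective(
    X: np.ndarray,
    W: np.ndarray,
    H: np.ndarray,
    config: SolverConfig,
    sp_h: float | None = None,
    alpha: float | None = None,
) -> tuple[float, float, float]:
    """(total, fidelity, penalty): squared Frobenius reconstruction error
    plus the weighted sparsity deviation of H. ``alpha`` overrides the
    config's (possibly auto-resolved) penalty weight; the solver passes the
    annealed weight of the current iteration."""
    X = X.values if isinstance(X, ImageMatrix) else np.asarray(X)
    if X.shape != (W.shape[0], H.shape[1]) or W.shape[1] != H.shape[0]:
        raise ValueError("shape mismatch between X, W, H")
    if alpha is None:
        alpha = config.resolved_alpha(X.shape[0])
    R = X - W @ H
    fidelity = float(np.sum(R * R))
    penalty = (
        _penalty(H, config, _resolve_sp(config, sp_h), alpha) if alpha > 0 else 0.0
    )
    return fidelity + penalty, fidelity, penalty


def _sparseness_grad(row: np.ndarray) -> np.ndarray:
    # d/dv of (sqrt(n) - L1/L2)/(sqrt(n)-1) for v >= 0, v != 0
    n = row.size
    l2 = np.linalg.norm(row)
    l1 = row.sum()
    return -(1.0 / (np.sqrt(n) - 1.0)) * (1.0 / l2 - l1 * row / l2**3)


def update_H(
    X: np.ndarray,
    W: np.ndarray,
    H: np.ndarray,
    config: SolverConfig,
    sp_h: float | None = None,
    exact: bool = False,
    alpha: float | None = None,
) -> tuple[np.ndarray, float]:
    """One projected-gradient step on H.

    Descend the objective gradient with a backtracking line search; each
    candidate is projected (entries clipped at zero, then the sparseness
    projection — two-sided when ``exact``, floor otherwise) *before* the
    acceptance test, so the accepted step never increases the objective.
    Returns (H, 0.0) when the line search exhausts its halvings — the
    caller sees the stall via the zero step.
    """
    X = X.values if isinstance(X, ImageMatrix) else np.asarray(X)
    sp = _resolve_sp(config, sp_h)
    if alpha is None:
        alpha = config.resolved_alpha(X.shape[0])
    WtW = W.T @ W
    grad = 2.0 * (WtW @ H - W.T @ X)
    # while the two-sided projection pins every row at sp_h the penalty is
    # identically ~0 and its gradient would only fight the projection, so
    # the soft pressure enters the descent direction after that phase
    if alpha > 0 and not exact:
        for i, row in enumerate(H):
            if not np.any(row):
                continue
            if config.penalty_form == "squared":
                dev = row_sparseness(row) - sp
                grad[i] += alpha * 2.0 * dev * _sparseness_grad(row)
            else:  # linear: constant downward pressure on row sparseness
                grad[i] += alpha * _sparseness_grad(row)
    lipschitz = 2.0 * np.linalg.norm(WtW, 2)
    init, shrink, max_halvings = config.line_search
    step = init / max(lipschitz, np.finfo(float).tiny)
    f0, _, _ = objective(X, W, H, config, sp, alpha)
    for _ in range(max_halvings + 1):
        cand = np.clip(H - step * grad, 0.0, None)
        if exact:
            cand = _project_rows(cand, sp, exact=True)
        elif config.enforce_floor:
            cand = _project_rows(cand, sp, exact=False)
        f, _, _ = objective(X, W, cand, config, sp, alpha)
        if f <= f0:
            return cand, step
        step *= shrink
    # stalled: keep H, but still honor the sparseness constraint (a no-op
    # whenever H already satisfies it, as it does inside the solver loop)
    if exact:
        return _project_rows(H, sp, exact=True), 0.0
    if config.enforce_floor:
        return _project_rows(H, sp, exact=False), 0.0
    return H, 0.0


def update_W(X: np.ndarray, W: np.ndarray, H: np.ndarray) -> np.ndarray:
    """Lee-Seung multiplicative update of the abundances:
    ``W <- W * (X H^T) / (W H H^T + eps)``. Never increases the
    reconstruction error and preserves nonnegativity (zero entries stay
    zero)."""
    X = X.values if isinstance(X, ImageMatrix) else np.asarray(X)
    eps = 1e-12 * max(float(X.max()), 1.0)
    numer = X @ H.T
    denom = W @ (H @ H.T) + eps
    return W * (numer / denom)


# ---------------------------------------------------------------------------
# the full pipeline

def _iterate(
    X: np.ndarray,
    W: np.ndarray,
    H: np.ndarray,
    config: SolverConfig,
    sp_h: float,
    constraint_iter: int,
    anneal_iter: int,
    max_iter: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, int, bool]:
    """Run the phased update schedule from a warm start; returns
    (W, H, objective trace, iterations, converged)."""
    alpha0 = config.resolved_alpha(X.shape[0])
    alpha = alpha0
    trace = [objective(X, W, H, config, sp_h, alpha)[0]]
    hold_until = constraint_iter + anneal_iter
    converged = False
    iterations = 0
    for it in range(1, max_iter + 1):
        exact = it <= constraint_iter
        if it > hold_until:
            alpha *= config.anneal_decay
        H, _ = update_H(X, W, H, config, sp_h, exact=exact, alpha=alpha)
        W = update_W(X, W, H)
        trace.append(objective(X, W, H, config, sp_h, alpha)[0])
        iterations = it
        annealed = alpha <= 1e-4 * alpha0 if alpha0 > 0 else not exact
        if annealed and abs(trace[-2] - trace[-1]) <= config.rel_tol * max(
            abs(trace[-2]), np.finfo(float).tiny
        ):
            converged = True
            break
    return W, H, np.asarray(trace), iterations, converged


def _closest_spectra(H: np.ndarray) -> tuple[tuple[int, int] | None, float]:
    r = H.shape[0]
    best_pair, best_sad = None, np.inf
    for i in range(r):
        if not np.any(H[i]):
            continue
        for j in range(i + 1, r):
            if not np.any(H[j]):
                continue
            cos = float(
                H[i] @ H[j] / (np.linalg.norm(H[i]) * np.linalg.norm(H[j]))
            )
            ang = float(np.arccos(np.clip(cos, -1.0, 1.0)))
            if ang < best_sad:
                best_pair, best_sad = (i, j), ang
    return best_pair, best_sad


def bingo_unmix(
    stack: ImageStack, r: int, config: SolverConfig | None = None
) -> FactorizationResult:
    """Blindly unmix an n-channel stack into r fluorophores.

    Pipeline: optional max-normalization of X -> NNDSVD initialization ->
    constraint phase (H rows held at sparseness exactly sp_h; projected
    gradient on H alternating with multiplicative W updates) -> release
    (projection relaxed to a floor; the linear sparsity penalty keeps a
    downward pressure that drifts the factors toward the least-sparse
    exact factorization, i.e. away from residual image crosstalk) ->
    penalty anneal and fidelity polish until the relative objective change
    drops below ``rel_tol`` or ``max_iter`` -> max-normalize H rows (scale
    folded into W) -> order components by peak channel. Deterministic end
    to end.
    """
    config = config or SolverConfig()
    mat = flatten(stack)
    n = mat.n
    if not 1 <= r <= min(mat.m, n):
        raise ValueError(
            f"r={r} violates the determined-system condition r <= min(m, n) "
            f"= {min(mat.m, n)} (need at least as many channels as fluorophores)"
        )
    X = mat.values
    if X.max() == 0:
        raise ValueError("all-zero stack cannot be unmixed")
    if config.normalize_input:
        X = X / X.max()
    sp_h = config.sp_h if config.sp_h is not None else estimate_sp_h(
        X, config.sp_margin
    )

    W, H = nndsvd(X, r, zero_fill=config.zero_fill)
    # a degenerate (all-zero) component would be multiplicatively locked;
    # seed it with a small uniform spectrum instead
    fill = X.mean() / 100.0
    for i in range(r):
        if not np.any(H[i]):
            H[i] = fill
        if not np.any(W[:, i]):
            W[:, i] = fill
    H = _project_rows(H, sp_h, exact=config.constraint_iter > 0)

    W, H, trace, iterations, converged = _iterate(
        X, W, H, config, sp_h,
        config.constraint_iter, config.anneal_iter, config.max_iter,
    )

    # deterministic split/merge repair: two spectra this close are one
    # fluorophore estimated twice, which means another went missing
    if config.rescue and r >= 2:
        best = (trace[-1], W, H, trace, iterations, converged)
        for _ in range(config.rescue_max):
            pair, ang = _closest_spectra(H)
            if pair is None or ang >= config.rescue_sad:
                break
            i, j = pair
            drop = j if W[:, i].sum() >= W[:, j].sum() else i
            keep = [k for k in range(r) if k != drop]
            Wk, Hk = W[:, keep].copy(), H[keep].copy()
            # brief refit so the surviving twin absorbs the shared structure
            Wk, Hk, _, _, _ = _iterate(
                X, Wk, Hk, config, sp_h, 0, min(40, config.max_iter), min(60, config.max_iter)
            )
            residual = np.clip(X - Wk @ Hk, 0.0, None)
            if residual.max() <= 1e-9 * X.max():
                break
            w0, h0 = nndsvd(residual, 1)
            W = np.concatenate([Wk, w0], axis=1)
            H = np.concatenate([Hk, h0], axis=0)
            H = _project_rows(H, sp_h, exact=True)
            W, H, trace, iterations, converged = _iterate(
                X, W, H, config, sp_h,
                config.constraint_iter // 2,
                config.anneal_iter // 2,
                config.max_iter // 2,
            )
            if trace[-1] < best[0]:
                best = (trace[-1], W, H, trace, iterations, converged)
        _, W, H, trace, iterations, converged = best
    logger.info(
        "bingo_unmix: r=%d sp_h=%.3f iter=%d converged=%s objective=%.6g "
        "min_row_sparseness=%.4f",
        r,
        sp_h,
        iterations,
        converged,
        trace[-1],
        min(row_sparseness(h) for h in H if np.any(h)),
    )

    # resolve the scale ambiguity: spectra peak at 1, scale lives in W
    row_max = H.max(axis=1)
    scale = np.where(row_max > 0, row_max, 1.0)
    H = H / scale[:, None]
    W = W * scale[None, :]
    # resolve the permutation ambiguity: ascending peak channel, ties by
    # descending total abundance
    peaks = np.argmax(H, axis=1)
    abundance = W.sum(axis=0)
    order = np.lexsort((-abundance, peaks))
    return FactorizationResult(
        W=W[:, order],
        H=H[order],
        X=X,
        height=stack.height,
        width=stack.width,
        objective_trace=np.asarray(trace),
        iterations=iterations,
        converged=converged,
        component_order=tuple(int(o) for o in order),
        sp_h=sp_h,
    )


# ---------------------------------------------------------------------------
# post-processing and baselines

def subtract_crosstalk(
    images: list[np.ndarray], target_index: int, donor_indices: list[int]
) -> list[np.ndarray]:
    """Remove residual bleed-through of donor components from one unmixed
    image: the target becomes ``max(0, target - sum_d c_d * donor_d)`` with
    each ``c_d`` the nonnegative least-squares coefficient of the donors
    regressed onto the target. Donor images are returned unchanged."""
    if target_index in donor_indices:
        raise ValueError("target and donor indices must be distinct")
    target = np.asarray(images[target_index], dtype=np.float64)
    donors = [np.asarray(images[d], dtype=np.float64) for d in donor_indices]
    for d, donor in zip(donor_indices, donors):
        if donor.shape == target.shape and np.array_equal(donor, target):
            raise ValueError(f"donor {d} is identical to the target image")
    D = np.stack([d.ravel() for d in donors], axis=1)
    coef, _ = scipy.optimize.nnls(D, target.ravel())
    cleaned = np.clip(target - (D @ coef).reshape(target.shape), 0.0, None)
    out = [np.asarray(im, dtype=np.float64).copy() for im in images]
    out[target_index] = cleaned
    return out


def lu_baseline(stack: ImageStack, S: MixingMatrix | np.ndarray) -> list[np.ndarray]:
    """Reference-spectrum linear unmixing: per-pixel nonnegative least
    squares of the channel vector onto the rows of the mixing matrix."""
    Smat = S.values if isinstance(S, MixingMatrix) else np.asarray(S, dtype=np.float64)
    mat = flatten(stack)
    if Smat.shape[1] != mat.n:
        raise ValueError("mixing matrix channel count does not match the stack")
    r = Smat.shape[0]
    if r > mat.n:
        raise ValueError("more fluorophores than channels (r <= n required)")
    if np.linalg.matrix_rank(Smat) < r:
        bad = _dependent_rows(Smat)
        raise ValueError(
            f"mixing matrix is rank-deficient; linearly dependent rows: {bad}"
        )
    A = Smat.T  # (n, r)
    X = mat.values
    abund = np.zeros((mat.m, r))
    nonzero = np.flatnonzero(X.any(axis=1))
    # identical pixel spectra share one NNLS solve
    uniq, inverse = np.unique(X[nonzero], axis=0, return_inverse=True)
    sols = np.stack([scipy.optimize.nnls(A, row)[0] for row in uniq])
    abund[nonzero] = sols[inverse]
    return unflatten(abund, stack.height, stack.width)


def _dependent_rows(S: np.ndarray) -> list[int]:
    bad = []
    for i in range(S.shape[0]):
        others = np.delete(S, i, axis=0)
        coef, *_ = np.linalg.lstsq(others.T, S[i], rcond=None)
        if np.linalg.norm(others.T @ coef - S[i]) <= 1e-10 * max(
            np.linalg.norm(S[i]), 1.0
        ):
            bad.append(i)
    return bad


def random_nmf(
    stack: ImageStack,
    r: int,
    seed: int = 0,
    max_iter: int = 500,
    normalize_input: bool = True,
) -> FactorizationResult:
    """Random-initialization, no-penalty NMF comparator (multiplicative
    Frobenius updates), packaged with the same normalization and component
    ordering as the main solver so metric comparisons are like for like."""
    import warnings

    from sklearn.decomposition import NMF
    from sklearn.exceptions import ConvergenceWarning

    mat = flatten(stack)
    X = mat.values
    if X.max() == 0:
        raise ValueError("all-zero stack cannot be unmixed")
    if normalize_input:
        X = X / X.max()
    model = NMF(
        n_components=r,
        init="random",
        solver="mu",
        beta_loss="frobenius",
        max_iter=max_iter,
        tol=1e-6,
        random_state=seed,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        W = model.fit_transform(X)
    H = model.components_
    row_max = H.max(axis=1)
    scale = np.where(row_max > 0, row_max, 1.0)
    H = H / scale[:, None]
    W = W * scale[None, :]
    peaks = np.argmax(H, axis=1)
    order = np.lexsort((-W.sum(axis=0), peaks))
    err = float(np.linalg.norm(X - W @ H) ** 2)
    return FactorizationResult(
        W=W[:, order],
        H=H[order],
        X=X,
        height=stack.height,
        width=stack.width,
        objective_trace=np.asarray([err]),
        iterations=model.n_iter_,
        converged=model.n_iter_ < max_iter,
        component_order=tuple(int(o) for o in order),
        sp_h=0.0,
    )
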