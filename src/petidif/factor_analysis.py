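"""Constrained factor analysis of dynamic PET images.

The model writes each voxel's signal as a nonnegative mixture of a few
temporal factor curves,

    S_i(t) = sum_k a_k(i) f_k(t) + e_i(t),

and identifies the blood factor (the image-derived input function, IDIF)
through physiological constraints:

* **P1** — all factor curves and factor images are nonnegative;
* **P2** — the blood factor has a single maximum located in the frame
  spanning 30–60 s (the pump injection makes the vascular peak land there),
  is non-decreasing before it and non-increasing after it;
* **P3** (tracer-dose mode only) — the blood factor stays similar to a
  template curve derived from presaturation (blocked-binding) scans, which
  protects the IDIF from the tracer-in-blood binding confound.

Solved in two steps: an uncentered 3-component PCA spans the temporal
subspace and K-means on the projected voxels provides initial factors
(cluster centroids); the factors are then refined by an alternating scheme —
exact nonnegative least squares for the factor images (support enumeration,
K ≤ 4), subspace least squares for the curves, constraint projection —
until the factors stop changing.  Presaturation scans use K = 3 factors
(blood, free tracer, excretion); tracer scans add a fourth factor for
specific binding plus the P3 constraint.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import isotonic_regression
from sklearn.cluster import KMeans

from .io import Curve, DynamicImage, FrameSchedule, body_mask


@dataclass
class FAConfig:
    """Knobs of the constrained factor analysis.

    ``peak_window`` is the (start, end) in seconds of the frame the blood
    factor must peak in; ``template_weight`` is the P3 shrinkage λ applied
    per iteration as ``f ← (1-λ) f + λ template`` (template rescaled to f's
    L2 norm).
    """

    n_components_pca: int = 3
    max_iterations: int = 200
    tolerance: float = 1e-4
    plateau_tolerance: float = 1e-5
    template_weight: float = 0.5
    kmeans_seed: int = 0
    kmeans_restarts: int = 10
    peak_window: tuple[float, float] = (30.0, 60.0)
    mask_threshold: float = 0.05

    def __post_init__(self) -> None:
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")


@dataclass
class FactorModel:
    """Result of the factor analysis.

    Factor curves carry the amplitude (concentration-like units); factor
    images are dimensionless weights normalised to unit maximum per factor.
    """

    factor_curves: np.ndarray  # (K, n_frames)
    factor_images: np.ndarray  # (K, nx, ny, nz)
    mask: np.ndarray  # 3D body mask the FA was run on
    schedule: FrameSchedule
    blood_index: int
    residual_norm: float
    n_iterations: int
    converged: bool
    residual_trajectory: np.ndarray = field(default_factory=lambda: np.array([]))

    @property
    def K(self) -> int:
        return self.factor_curves.shape[0]

    @property
    def blood_curve(self) -> Curve:
        return Curve(self.schedule.mids, self.factor_curves[self.blood_index], unit="arb")

    def factor_totals(self) -> np.ndarray:
        """Sum of each factor image over voxels (dimensionless weights)."""
        return self.factor_images.reshape(self.K, -1).sum(axis=1)


# --------------------------------------------------------------------------
# PCA subspace (uncentered — signals are nonnegative mixtures)
# --------------------------------------------------------------------------

def pca_subspace(voxel_tacs: np.ndarray, n_components: int) -> tuple[np.ndarray, np.ndarray]:
    """Top-variance temporal basis of a (n_voxels, n_frames) matrix.

    Returns (basis, projections): ``basis`` is (n_components, n_frames) with
    orthonormal rows; ``projections`` (n_voxels, n_components) are the
    least-squares coordinates of each voxel TAC in that basis.  No mean
    subtraction is applied, so nonnegative reconstructions stay reachable.
    """
    X = np.asarray(voxel_tacs, dtype=float)
    if X.ndim != 2:
        raise ValueError("voxel_tacs must be 2-D (voxels x frames)")
    n_vox, n_frames = X.shape
    if n_frames < n_components:
        raise ValueError("need at least as many frames as components")
    if n_vox < n_components:
        raise ValueError("need at least as many voxels as components")
    # frames << voxels: eigendecompose the small frame-space Gram matrix
    gram = X.T @ X
    vals, vecs = np.linalg.eigh(gram)
    order = np.argsort(vals)[::-1][:n_components]
    basis = vecs[:, order].T
    # sign convention: make each component predominantly nonnegative
    flip = np.sign(basis.sum(axis=1))
    flip[flip == 0] = 1.0
    basis = basis * flip[:, None]
    return basis, X @ basis.T


# --------------------------------------------------------------------------
# K-means initialisation
# --------------------------------------------------------------------------

def init_factors_kmeans(
    projections: np.ndarray,
    basis: np.ndarray,
    K: int,
    seed: int = 0,
    n_restarts: int = 10,
    max_retries: int = 5,
    apex: bool = True,
) -> np.ndarray:
    """Initial factor curves from K-means clustering in PCA space.

    k-means++ seeding with ``n_restarts`` restarts, deterministic for a given
    seed.  If any cluster comes back empty the clustering is re-seeded (a
    bounded number of times).

    With ``apex=False`` the cluster centroids are mapped back to frame space
    and returned.  By default (``apex=True``) each centroid is sharpened to
    its cluster's *apex*: the cluster member (of at least median signal norm)
    furthest, relative to its own norm, from the span of the other centroids.
    Cluster centroids are averages of mixed voxels and so sit inside the data
    cone; the apex voxels approximate its extreme rays, i.e. the purest
    expression of each underlying physiological signal — the apex-seeking
    idea of the oblique-FA lineage.  For K=1 the global mean TAC is returned.
    """
    if K > projections.shape[0]:
        raise ValueError("K exceeds the number of voxels")
    labels = None
    for attempt in range(max_retries):
        km = KMeans(n_clusters=K, n_init=n_restarts, random_state=seed + attempt)
        labels = km.fit_predict(projections)
        if len(np.unique(labels)) == K:
            break
    else:
        raise RuntimeError("K-means produced an empty cluster in every retry")
    centroids = km.cluster_centers_
    if not apex or K == 1:
        return centroids @ basis
    F0 = np.empty((K, basis.shape[1]))
    for k in range(K):
        others = centroids[[j for j in range(K) if j != k]]
        Q, _ = np.linalg.qr(others.T)
        members = projections[labels == k]
        norms = np.linalg.norm(members, axis=1)
        # keep dim but genuine voxels eligible while excluding noise-dominated ones
        strong = norms >= 0.25 * norms.max()
        cand, cand_norms = members[strong], norms[strong]
        resid = cand - (cand @ Q) @ Q.T
        score = np.linalg.norm(resid, axis=1) / cand_norms
        F0[k] = cand[np.argmax(score)] @ basis
    return F0


# --------------------------------------------------------------------------
# Constraint P2: timed unimodal peak
# --------------------------------------------------------------------------

def _peak_frame(schedule: FrameSchedule, window: tuple[float, float]) -> int:
    return schedule.frame_covering(window[0], window[1])


def enforce_peak_constraint(
    values: np.ndarray,
    schedule: FrameSchedule,
    window: tuple[float, float] = (30.0, 60.0),
    peak_frame: int | None = None,
) -> np.ndarray:
    """Least-squares projection onto the P2 cone: non-decreasing up to the
    peak frame, maximal there, non-increasing after; clipped nonnegative.

    Implemented with pool-adjacent-violators isotonic regression on each side
    of the peak frame (the peak frame belongs to both monotone segments; its
    value resolves to the larger of the two fits, which keeps both segments
    monotone and the maximum at the peak frame).
    """
    y = np.asarray(values, dtype=float)
    if peak_frame is None:
        peak_frame = _peak_frame(schedule, window)  # raises if no such frame
    p = int(peak_frame)
    out = np.empty_like(y)
    pre = isotonic_regression(y[: p + 1], increasing=True).x
    post = isotonic_regression(y[p:], increasing=False).x
    out[:p] = pre[:-1]
    out[p + 1:] = post[1:]
    out[p] = max(pre[-1], post[0])
    return np.clip(out, 0.0, None)


def blood_seed_curve(
    denoised_tacs: np.ndarray,
    schedule: FrameSchedule,
    window: tuple[float, float] = (30.0, 60.0),
    peak_frame: int | None = None,
    n_voxels: int = 20,
    min_peak_fraction: float = 0.3,
) -> np.ndarray:
    """Blood-like initial curve from the most P2-feasible hot voxels.

    Blood-pool voxels are the ones whose TACs peak early (in the 30-60 s
    frame) and decay monotonically — exactly the P2 constraint.  Among
    voxels whose early peak reaches ``min_peak_fraction`` of the hottest
    early peak, the ``n_voxels`` TACs closest (relative L2) to their own P2
    projection are averaged.  Run on subspace-denoised TACs this is robust
    to both noise and an unlucky clustering that leaves the (small) blood
    pool without a cluster of its own.
    """
    X = np.asarray(denoised_tacs, dtype=float)
    if peak_frame is None:
        peak_frame = _peak_frame(schedule, window)
    p = int(peak_frame)
    early_peak = X[:, p]
    eligible = np.flatnonzero(early_peak >= min_peak_fraction * early_peak.max())
    dists = np.empty(len(eligible))
    for j, i in enumerate(eligible):
        x = X[i]
        norm = np.linalg.norm(x)
        if norm == 0:
            dists[j] = np.inf
            continue
        proj = enforce_peak_constraint(x, schedule, window, peak_frame)
        dists[j] = np.linalg.norm(x - proj) / norm
    best = eligible[np.argsort(dists)[: min(n_voxels, len(eligible))]]
    return X[best].mean(axis=0)


def identify_blood_factor(
    factors: np.ndarray,
    schedule: FrameSchedule,
    window: tuple[float, float] = (30.0, 60.0),
    peak_frame: int | None = None,
) -> int:
    """Index of the factor best meeting P2: smallest relative L2 distance to
    its P2 projection; ties broken by the earlier peak time."""
    factors = np.atleast_2d(np.asarray(factors, dtype=float))
    if factors.shape[0] < 2:
        raise ValueError("need at least 2 factors to identify the blood factor")
    mids = schedule.mids
    dists, peaks = [], []
    for f in factors:
        norm = np.linalg.norm(f)
        if norm == 0:
            dists.append(np.inf)
            peaks.append(np.inf)
            continue
        proj = enforce_peak_constraint(f, schedule, window, peak_frame)
        dists.append(np.linalg.norm(f - proj) / norm)
        peaks.append(mids[int(np.argmax(f))])
    dists, peaks = np.asarray(dists), np.asarray(peaks)
    best = dists.min()
    candidates = np.flatnonzero(dists <= best + 1e-12)
    return int(candidates[np.argmin(peaks[candidates])])


# --------------------------------------------------------------------------
# Exact nonnegative least squares for small K (support enumeration)
# --------------------------------------------------------------------------

def _nnls_images(factors: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Per-voxel exact NNLS weights A >= 0 minimising ||X - A F||.

    With K <= 4 factors the 2^K candidate supports are enumerated; for each
    support the unconstrained least-squares solution is computed for all
    voxels at once and the best feasible candidate wins.  The feasible
    minimiser over supports is the global NNLS optimum.
    """
    F = np.asarray(factors, dtype=float)
    K = F.shape[0]
    n_vox = X.shape[0]
    best_res = np.einsum("ij,ij->i", X, X)  # empty support: A = 0
    best_A = np.zeros((n_vox, K))
    for r in range(1, K + 1):
        for support in itertools.combinations(range(K), r):
            Fs = F[list(support)]
            G = Fs @ Fs.T
            try:
                Ginv = np.linalg.inv(G)
            except np.linalg.LinAlgError:
                Ginv = np.linalg.pinv(G)
            coef = X @ Fs.T @ Ginv  # (n_vox, r)
            feasible = (coef >= -1e-12).all(axis=1)
            if not feasible.any():
                continue
            resid = X - coef @ Fs
            res = np.einsum("ij,ij->i", resid, resid)
            better = feasible & (res < best_res - 1e-12 * best_res)
            if better.any():
                best_res[better] = res[better]
                best_A[better] = 0.0
                best_A[np.ix_(better, list(support))] = np.clip(coef[better], 0.0, None)
    return best_A


# --------------------------------------------------------------------------
# Iterative refinement
# --------------------------------------------------------------------------

def refine_factors(
    X: np.ndarray,
    init_factors: np.ndarray,
    basis: np.ndarray,
    schedule: FrameSchedule,
    blood_index: int,
    config: FAConfig | None = None,
    template: Curve | None = None,
) -> tuple[np.ndarray, np.ndarray, float, int, bool, np.ndarray]:
    """Alternating refinement under P1/P2(/P3).

    Per iteration: (a) exact NNLS for the factor images given the curves;
    (b) least-squares re-estimation of the curves within the PCA subspace;
    (c) nonnegativity clip, P2 projection of the blood factor and, when a
    template is given, P3 shrinkage of the blood factor toward it.  Stops
    when no factor changes by more than the relative tolerance.

    Returns (factors, images, residual_norm, n_iterations, converged,
    residual_trajectory); the trajectory interleaves the residual RMS before
    and after each NNLS step.
    """
    cfg = config or FAConfig()
    F = np.array(init_factors, dtype=float)
    K, n_frames = F.shape
    F = np.clip(F, 0.0, None)
    peak_frame = _peak_frame(schedule, cfg.peak_window)
    F[blood_index] = enforce_peak_constraint(F[blood_index], schedule, peak_frame=peak_frame)

    tmpl = None
    if template is not None:
        t = np.asarray(template.values, dtype=float)
        if len(t) != n_frames:
            raise ValueError("template length does not match the frame schedule")
        tmpl = enforce_peak_constraint(t, schedule, peak_frame=peak_frame)

    n_vox = X.shape[0]
    A = np.zeros((n_vox, K))
    trajectory: list[float] = []
    converged = False
    plateau = 0
    prev_resid = np.inf
    it = 0
    for it in range(1, cfg.max_iterations + 1):
        F_prev = F.copy()
        # (a) images by exact NNLS — never increases the residual
        pre = X - A @ F
        trajectory.append(float(np.sqrt(np.mean(pre * pre))))
        A = _nnls_images(F, X)
        post = X - A @ F
        resid_now = float(np.sqrt(np.mean(post * post)))
        trajectory.append(resid_now)
        # residual plateau: once the fit stops improving, further factor
        # motion is a noise-driven walk along a degenerate direction
        if prev_resid - resid_now < cfg.plateau_tolerance * max(resid_now, 1e-300):
            plateau += 1
            if plateau >= 3:
                converged = True
                break
        else:
            plateau = 0
        prev_resid = resid_now
        # (b) curves by least squares within the PCA subspace
        coeffs, *_ = np.linalg.lstsq(A, X @ basis.T, rcond=None)
        F = coeffs @ basis
        # (c) constraint projections
        F = np.clip(F, 0.0, None)
        F[blood_index] = enforce_peak_constraint(F[blood_index], schedule, peak_frame=peak_frame)
        if tmpl is not None:
            fb = F[blood_index]
            nb, nt = np.linalg.norm(fb), np.linalg.norm(tmpl)
            if nb > 0 and nt > 0:
                lam = cfg.template_weight
                F[blood_index] = (1 - lam) * fb + lam * tmpl * (nb / nt)
        # convergence: max relative L2 change of any factor
        denom = np.linalg.norm(F_prev, axis=1)
        denom[denom == 0] = 1.0
        change = np.linalg.norm(F - F_prev, axis=1) / denom
        if change.max() < cfg.tolerance:
            converged = True
            break
    if not converged:
        warnings.warn("factor refinement did not converge; returning best iterate")
    # final images consistent with the final (constraint-satisfying) curves
    A = _nnls_images(F, X)
    resid = X - A @ F
    residual_norm = float(np.sqrt(np.mean(resid * resid)))
    return F, A, residual_norm, it, converged, np.asarray(trajectory)


# --------------------------------------------------------------------------
# Full extraction
# --------------------------------------------------------------------------

def extract_factors(
    image: DynamicImage,
    mode: str = "tracer",
    template: Curve | None = None,
    config: FAConfig | None = None,
    mask: np.ndarray | None = None,
) -> FactorModel:
    """Run the whole constrained FA chain on a dynamic image.

    ``mode='presaturation'`` extracts K=3 factors with P1+P2;
    ``mode='tracer'`` extracts K=4 factors with P1+P2+P3 and requires a
    presaturation-derived template curve.
    """
    cfg = config or FAConfig()
    if mode == "presaturation":
        K = 3
    elif mode == "tracer":
        K = 4
        if template is None:
            raise ValueError("tracer mode requires a presaturation-derived template curve")
    else:
        raise ValueError(f"unknown mode {mode!r}")

    if mask is None:
        mask = body_mask(image, cfg.mask_threshold)
    X = image.voxels[mask]
    # K factors need a K-dimensional temporal span; presaturation (K=3) keeps
    # the canonical 3-component subspace
    basis, proj = pca_subspace(X, max(cfg.n_components_pca, K))
    F0 = init_factors_kmeans(proj, basis, K, seed=cfg.kmeans_seed, n_restarts=cfg.kmeans_restarts)
    blood_index = identify_blood_factor(F0, image.schedule, cfg.peak_window)
    # a small blood pool can fail to earn its own cluster; re-seed the
    # identified factor from the most P2-feasible hot voxels directly
    F0[blood_index] = blood_seed_curve(proj @ basis, image.schedule, cfg.peak_window)
    F, A, residual_norm, n_it, converged, traj = refine_factors(
        X, F0, basis, image.schedule, blood_index, cfg, template
    )
    # scale convention: images are weights with unit maximum, curves carry scale
    for k in range(K):
        m = A[:, k].max()
        if m > 0:
            A[:, k] /= m
            F[k] *= m
    images = np.zeros((K,) + image.spatial_shape)
    images[:, mask] = A.T
    return FactorModel(
        factor_curves=F,
        factor_images=images,
        mask=mask,
        schedule=image.schedule,
        blood_index=blood_index,
        residual_norm=residual_norm,
        n_iterations=n_it,
        converged=converged,
        residual_trajectory=traj,
    )
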