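"""Time-difference conductivity imaging on a hexahedral voxel grid.

The inverse problem is zeroth-order Tikhonov on an axis-aligned voxel grid
clipped to the brain: delta-sigma = (J^T J + lambda c I)^(-1) J^T dz with
c the mean diagonal of J^T J (so lambda is a dimensionless, mesh-independent
knob), the regularization weight chosen by channel-wise cross-validation,
and images expressed as t-scores: each voxel's reconstructed change divided
by its noise SD, propagated exactly from the per-channel baseline noise
through the linear inverse map M = (J^T J + lambda c I)^(-1) J^T as
sqrt(diag(M Sigma M^T)).

With many more voxels than channels the dual (Gram) form is used
throughout: one eigendecomposition of G = J J^T serves hyperparameter
selection, reconstruction of every frame, and exact noise propagation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg as la
import scipy.sparse as sp

from .forward import JacobianMatrix
from .geometry import HeadModel, element_centroids, tet_volumes

log = logging.getLogger(__name__)

__all__ = [
    "InverseGrid",
    "ImageSeries",
    "build_inverse_grid",
    "coarsen_jacobian",
    "TikhonovImager",
    "select_hyperparameter",
    "tikhonov_reconstruct",
    "noise_weight_tscore",
    "reconstruct_sequence",
]

DISPLAY_T_THRESHOLD = 3.0  # sigma; voxels below are zeroed in exports


@dataclass
class InverseGrid:
    """Axis-aligned voxel grid with a tetrahedron->voxel aggregation map.

    ``weights`` is (n_elements, n_voxels) sparse; entry (e, v) is the volume
    of element e attributed to voxel v (split over 4 interior quadrature
    points per element).  Per-element rows sum to the element volume, so
    total volume is conserved exactly; per-voxel columns approximate the
    intersected volume.  Only voxels receiving weight are in the mask.
    """

    voxel_size: float  # mm
    origin: np.ndarray  # mm corner of voxel (0,0,0)
    shape: tuple[int, int, int]
    mask_indices: np.ndarray  # (n_voxels,) flat indices into the full grid
    centers: np.ndarray  # (n_voxels, 3) mm
    weights: sp.csr_matrix  # (n_elements, n_voxels)

    @property
    def n_voxels(self) -> int:
        return self.mask_indices.size

    @property
    def voxel_volumes(self) -> np.ndarray:
        """Intersected volume per masked voxel (mm^3)."""
        return np.asarray(self.weights.sum(axis=0)).ravel()

    def embed(self, values: np.ndarray) -> np.ndarray:
        """Scatter masked-voxel values into the full 3D grid (zeros outside)."""
        full = np.zeros(int(np.prod(self.shape)), dtype=float)
        full[self.mask_indices] = values
        return full.reshape(self.shape)

    @property
    def affine(self) -> np.ndarray:
        A = np.eye(4)
        A[:3, :3] *= self.voxel_size
        A[:3, 3] = self.origin
        return A


def build_inverse_grid(model: HeadModel, voxel_size: float = 2.0) -> InverseGrid:
    """Voxelize the brain and build the deterministic aggregation map.

    Each tetrahedron's volume is split equally over its four vertex-centroid
    midpoints and binned into the voxels containing them; a tetrahedron
    therefore always maps to at least one voxel, and the map is invariant to
    element ordering.
    """
    if voxel_size < model.edge_length / 2.0:
        raise ValueError("voxel size must be at least half the mesh edge length")
    verts = model.vertices
    lo = verts.min(axis=0) - 0.5 * voxel_size
    hi = verts.max(axis=0) + 0.5 * voxel_size
    shape = tuple(int(np.ceil((hi[i] - lo[i]) / voxel_size)) for i in range(3))

    tets = model.tetrahedra
    vols = np.abs(tet_volumes(verts, tets))
    cent = verts[tets].mean(axis=1)
    n_e = tets.shape[0]

    rows, cols, vals = [], [], []
    for i in range(4):
        q = 0.5 * (verts[tets[:, i]] + cent)  # interior quadrature point
        ijk = np.floor((q - lo) / voxel_size).astype(np.int64)
        ijk = np.clip(ijk, 0, np.array(shape) - 1)
        flat = np.ravel_multi_index((ijk[:, 0], ijk[:, 1], ijk[:, 2]), shape)
        rows.append(np.arange(n_e))
        cols.append(flat)
        vals.append(vols / 4.0)
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    vals = np.concatenate(vals)

    full = sp.coo_matrix((vals, (rows, cols)), shape=(n_e, int(np.prod(shape)))).tocsc()
    occupancy = np.asarray(full.sum(axis=0)).ravel()
    mask = np.flatnonzero(occupancy > 0)
    if mask.size == 0:
        raise ValueError("empty brain mask: no voxel intersects the mesh")
    W = full[:, mask].tocsr()

    ii, jj, kk = np.unravel_index(mask, shape)
    centers = lo + (np.column_stack([ii, jj, kk]) + 0.5) * voxel_size
    return InverseGrid(
        voxel_size=float(voxel_size),
        origin=lo,
        shape=shape,
        mask_indices=mask,
        centers=centers,
        weights=W,
    )


def coarsen_jacobian(J: JacobianMatrix | np.ndarray, grid: InverseGrid) -> np.ndarray:
    """Aggregate the element-space Jacobian onto voxels.

    J_vox[ch, v] = sum_e (w(e,v)/vol_e) J[ch, e]: the volume-fraction
    weighting preserves the response to any voxel-wise-uniform perturbation
    exactly (rows of the fraction matrix sum to 1).  Orphan voxels cannot
    occur by construction of the grid; orphan *elements* are impossible
    because every element carries weight.
    """
    entries = J.entries if isinstance(J, JacobianMatrix) else np.asarray(J)
    vol_e = np.asarray(grid.weights.sum(axis=1)).ravel()
    frac = sp.diags(1.0 / vol_e) @ grid.weights  # (n_e, n_vox), rows sum to 1
    return np.asarray(entries @ frac)


@dataclass
class ImageSeries:
    """Per-second reconstructed volumes with their noise-referenced t-scores."""

    grid: InverseGrid
    times: np.ndarray  # (n_frames,) s
    delta_sigma: np.ndarray  # (n_voxels, n_frames) S/m
    tscore: np.ndarray  # (n_voxels, n_frames)
    lam: float
    noise_sd: np.ndarray  # per-channel dz noise SD used for weighting
    voxel_noise_sd: np.ndarray | None = None  # (n_voxels,)
    cv_curve: tuple[np.ndarray, np.ndarray] | None = None  # (lambdas, cv error)

    @property
    def n_frames(self) -> int:
        return self.times.size

    def frame(self, t: float, kind: str = "tscore") -> np.ndarray:
        i = int(np.argmin(np.abs(self.times - t)))
        arr = self.tscore if kind == "tscore" else self.delta_sigma
        return arr[:, i]

    def thresholded(self, threshold: float = DISPLAY_T_THRESHOLD) -> np.ndarray:
        """t-score frames with |t| below the display threshold zeroed."""
        out = self.tscore.copy()
        out[np.abs(out) < threshold] = 0.0
        return out


class TikhonovImager:
    """Zeroth-order Tikhonov inverse in the dual (Gram) form.

    One symmetric eigendecomposition of G = J J^T (channels x channels)
    yields, for any lambda: reconstructions x = J^T Q (g + lam c)^(-1) Q^T dz,
    cross-validated hyperparameter selection on held-out channels, and the
    exact propagated voxel noise diag(M Sigma M^T).
    """

    def __init__(self, J_vox: np.ndarray):
        self.J = np.asarray(J_vox, dtype=float)
        self.n_ch, self.n_vox = self.J.shape
        G = self.J @ self.J.T
        self.c = float(np.trace(G) / self.n_vox)  # = mean diag(J^T J)
        self.evals, self.Q = la.eigh(G)
        self.evals = np.maximum(self.evals, 0.0)
        self._P: np.ndarray | None = None  # J^T Q, formed lazily (big)
        self._cv_cache: dict = {}  # fold eigendecompositions, data-independent

    @property
    def P(self) -> np.ndarray:
        if self._P is None:
            self._P = self.J.T @ self.Q
        return self._P

    def reconstruct(self, dz: np.ndarray, lam: float) -> np.ndarray:
        """x = J^T (G + lam c I)^(-1) dz for a vector or (n_ch, n_frames)."""
        dz = np.asarray(dz, dtype=float)
        if dz.shape[0] != self.n_ch:
            raise ValueError(
                f"dz has {dz.shape[0]} channels but the Jacobian has {self.n_ch} rows"
            )
        alpha = self.Q @ ((self.Q.T @ dz).T / (self.evals + lam * self.c)).T
        return self.J.T @ alpha

    def voxel_noise_sd(self, noise_sd: np.ndarray | float, lam: float) -> np.ndarray:
        """Exact sqrt(diag(M Sigma M^T)) for Sigma = diag(noise_sd^2)."""
        sd = np.broadcast_to(np.asarray(noise_sd, dtype=float), (self.n_ch,))
        if np.any(sd <= 0):
            eps = max(np.max(sd), 1.0) * 1e-12
            warnings.warn("zero noise SD on some channels: flooring at eps", stacklevel=2)
            sd = np.maximum(sd, eps)
        # M = J^T Q D Q^T with D = 1/(g + lam c); diag(M Sigma M^T) =
        # rowsums( (P D Q^T Sigma^(1/2))^2 ) computed without forming M.
        D = 1.0 / (self.evals + lam * self.c)
        B = (self.Q * D[None, :]).T * sd[None, :]  # (n_ch, n_ch): D Q^T Sigma^1/2
        M_half = self.P @ B  # (n_vox, n_ch) = M Sigma^(1/2)
        return np.sqrt(np.einsum("ij,ij->i", M_half, M_half))

    def cv_error(
        self,
        dz: np.ndarray,
        lambdas: np.ndarray,
        n_folds: int = 10,
        fold_seed: int = 0,
    ) -> np.ndarray:
        """Cross-validated prediction error of held-out channel voltages.

        Folds partition channels; for each fold, the model fitted on the
        training channels predicts the held-out voltages through the Gram
        matrix only (no voxel-space work).  Deterministic given fold_seed.
        Returns the per-fold mean-squared prediction error, shaped
        (n_folds, n_lambdas).
        """
        dz = np.asarray(dz, dtype=float)
        key = (int(n_folds), int(fold_seed))
        if key not in self._cv_cache:
            G = self.Q @ (self.Q * self.evals[None, :]).T  # reconstitute G once
            rng = np.random.default_rng(fold_seed)
            perm = rng.permutation(self.n_ch)
            cache = []
            for hold in np.array_split(perm, n_folds):
                train = np.setdiff1d(perm, hold)
                w, V = la.eigh(G[np.ix_(train, train)])
                cache.append((train, hold, np.maximum(w, 0.0), V, G[np.ix_(hold, train)]))
            self._cv_cache[key] = cache
        per_fold = np.zeros((n_folds, lambdas.size))
        for fi, (train, hold, w, V, Ght) in enumerate(self._cv_cache[key]):
            proj = V.T @ dz[train]
            for li, lam in enumerate(lambdas):
                alpha = V @ (proj / (w + lam * self.c))
                pred = Ght @ alpha
                per_fold[fi, li] = float(np.mean((pred - dz[hold]) ** 2))
        return per_fold

    def select_lambda(
        self,
        dz: np.ndarray,
        lambdas: np.ndarray | None = None,
        n_folds: int = 10,
        fold_seed: int = 0,
        noise_sd: np.ndarray | float | None = None,
    ) -> tuple[float, np.ndarray, np.ndarray]:
        """One-standard-error CV choice over a log grid; discrepancy fallback.

        Returns (lambda, grid, cv_curve).  The selected weight is the
        largest lambda whose CV error stays within one fold-wise standard
        error of the minimum -- the usual parsimony rule, which guards
        against the occasional razor-thin minimum at vanishing
        regularization.  A curve that keeps falling towards the top of the
        grid (pure-noise data) simply saturates there; a curve that is
        monotone *increasing* with an available noise level triggers a
        discrepancy-principle fallback with a warning.
        """
        if lambdas is None:
            lambdas = np.logspace(-8, 2, 50)
        if self.n_ch < 20:
            raise ValueError("hyperparameter selection needs at least 20 channels")
        per_fold = self.cv_error(dz, lambdas, n_folds=n_folds, fold_seed=fold_seed)
        err = per_fold.mean(axis=0)
        se = per_fold.std(axis=0, ddof=1) / np.sqrt(per_fold.shape[0])
        i = int(np.argmin(err))
        if i == lambdas.size - 1 and noise_sd is not None and err[0] < err[-1]:
            warnings.warn("monotone increasing CV curve: falling back to discrepancy "
                          "principle", stacklevel=2)
            sd = np.broadcast_to(np.asarray(noise_sd, float), (self.n_ch,))
            target = float(np.sum(sd**2))
            for lam in lambdas:
                x = self.reconstruct(dz, lam)
                if float(np.sum((self.J @ x - dz) ** 2)) >= target:
                    return float(lam), lambdas, err
        admissible = np.flatnonzero(err <= err[i] + se[i])
        j = int(admissible.max())
        return float(lambdas[j]), lambdas, err


def select_hyperparameter(
    J_vox: np.ndarray,
    dz_vector: np.ndarray,
    noise_sd: np.ndarray | float | None = None,
    lambdas: np.ndarray | None = None,
    n_folds: int = 10,
    fold_seed: int = 0,
) -> tuple[float, np.ndarray, np.ndarray]:
    """Cross-validated Tikhonov weight for one (Jacobian, data) pair."""
    imager = TikhonovImager(J_vox)
    return imager.select_lambda(
        dz_vector, lambdas, n_folds=n_folds, fold_seed=fold_seed, noise_sd=noise_sd
    )


def tikhonov_reconstruct(J_vox: np.ndarray, dz: np.ndarray, lam: float) -> np.ndarray:
    """delta-sigma = (J^T J + lam c I)^(-1) J^T dz, c = mean diag(J^T J).

    Solved in whichever of the primal/dual forms is smaller; they are
    algebraically identical.  ``dz`` may be a vector or (n_ch, n_frames).
    """
    J = np.asarray(J_vox, dtype=float)
    dz = np.asarray(dz, dtype=float)
    n_ch, n_vox = J.shape
    if dz.shape[0] != n_ch:
        raise ValueError(f"dz length {dz.shape[0]} does not match {n_ch} channels")
    if n_vox <= n_ch:
        A = J.T @ J
        c = float(np.trace(A) / n_vox)
        A[np.diag_indices_from(A)] += lam * c
        return la.solve(A, J.T @ dz, assume_a="pos")
    G = J @ J.T
    c = float(np.trace(G) / n_vox)
    G[np.diag_indices_from(G)] += lam * c
    return J.T @ la.solve(G, dz, assume_a="pos")


def noise_weight_tscore(
    delta_sigma: np.ndarray,
    imager: TikhonovImager,
    noise_sd: np.ndarray | float,
    lam: float,
    frame_noise_scale: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """t-score frames: reconstructed change / propagated voxel noise SD.

    ``frame_noise_scale`` optionally multiplies the voxel noise frame by
    frame (edge frames of a finite zero-phase-filtered block are noisier
    than interior ones).  Returns (tscore, voxel_noise_sd); finite
    everywhere in the mask.
    """
    vsd = imager.voxel_noise_sd(noise_sd, lam)
    vsd = np.maximum(vsd, np.max(vsd) * 1e-12 + 1e-300)
    ds = np.atleast_2d(delta_sigma.T).T if delta_sigma.ndim == 1 else delta_sigma
    t = ds / vsd[:, None]
    if frame_noise_scale is not None and delta_sigma.ndim > 1:
        t = t / np.asarray(frame_noise_scale)[None, : t.shape[1]]
    return (t.ravel() if delta_sigma.ndim == 1 else t), vsd


def reconstruct_sequence(
    dz_frames: np.ndarray,
    frame_times: np.ndarray,
    imager: TikhonovImager,
    grid: InverseGrid,
    noise_sd: np.ndarray | float,
    lam: float | None = None,
    n_folds: int = 10,
    fold_seed: int = 0,
    cv_frame: int | None = None,
    frame_noise_scale: np.ndarray | None = None,
) -> ImageSeries:
    """Reconstruct one t-score volume per second over a block.

    ``dz_frames`` is (n_channels, n_frames) of baseline-referenced voltage
    changes in Jacobian channel order (rejected channels must already be
    dropped from both).  The hyperparameter is selected once per block on
    the frame with the largest dz norm unless given.
    """
    dz_frames = np.asarray(dz_frames, dtype=float)
    cv_curve = None
    if lam is None:
        if cv_frame is None:
            # pick the strongest interior frame (block edges carry the
            # residual filter transients)
            norms = np.linalg.norm(dz_frames, axis=0)
            guard = min(5, dz_frames.shape[1] // 4)
            core = norms[guard: dz_frames.shape[1] - guard]
            j = int(np.argmax(core)) + guard
        else:
            j = cv_frame
        lam, grid_l, err = imager.select_lambda(
            dz_frames[:, j], n_folds=n_folds, fold_seed=fold_seed, noise_sd=noise_sd
        )
        cv_curve = (grid_l, err)
        log.info("selected lambda = %.3g (frame %d)", lam, j)
    ds = imager.reconstruct(dz_frames, lam)
    t, vsd = noise_weight_tscore(ds, imager, noise_sd, lam, frame_noise_scale)
    return ImageSeries(
        grid=grid,
        times=np.asarray(frame_times, dtype=float),
        delta_sigma=ds,
        tscore=t,
        lam=float(lam),
        noise_sd=np.broadcast_to(np.asarray(noise_sd, float), (imager.n_ch,)).copy(),
        voxel_noise_sd=vsd,
        cv_curve=cv_curve,
    )
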