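"""Pigment component separation: colour-plane PCA, shading removal, 2-D ICA.

The two-pigment skin model places (shading-free) optical densities on a 2-D
plane spanned by the melanin and hemoglobin absorbance vectors. The stages:

1. ``estimate_color_plane`` — PCA of densities in a small, evenly lit region
   gives that plane.
2. ``remove_shading`` — every pixel's density is decomposed exactly as
   ``origin + u*basis_u + v*basis_v + s*illum``: an *oblique* projection along
   the illumination direction onto the plane. ``s`` is the shading term.
3. ``estimate_pigment_vectors`` — fixed-point ICA in the 2-D plane
   coordinates recovers the two statistically independent pigment axes.
4. ``project_concentrations`` — a 2x2 solve converts plane coordinates to
   melanin/hemoglobin concentrations.

``separate`` composes the four.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .types import ConcentrationMap, PigmentBasis, SkinImage


class ConvergenceError(RuntimeError):
    """ICA fixed-point iteration failed to converge."""


@dataclass
class ColorPlane:
    """The skin colour distribution plane in optical-density space.

    ``basis_u``/``basis_v`` are orthonormal in-plane directions (top-2
    principal components), ``origin`` the mean density of the training region,
    ``normal`` the unit plane normal. ``explained_variance`` holds the
    per-component variance fractions from the PCA.
    """

    basis_u: np.ndarray
    basis_v: np.ndarray
    origin: np.ndarray
    normal: np.ndarray
    explained_variance: np.ndarray | None = None

    def __post_init__(self) -> None:
        for name in ("basis_u", "basis_v", "origin", "normal"):
            v = np.asarray(getattr(self, name), dtype=float)
            if v.shape != (3,):
                raise ValueError(f"{name} must be a 3-vector")
            setattr(self, name, v)
        if abs(np.dot(self.basis_u, self.basis_v)) > 1e-8:
            raise ValueError("basis_u and basis_v must be orthogonal")
        for name in ("basis_u", "basis_v", "normal"):
            if abs(np.linalg.norm(getattr(self, name)) - 1.0) > 1e-8:
                raise ValueError(f"{name} must be unit norm")

    def coords_of(self, density: np.ndarray) -> np.ndarray:
        """Orthogonal in-plane coordinates of density vectors (no shading)."""
        rel = density - self.origin
        return np.stack([rel @ self.basis_u, rel @ self.basis_v], axis=-1)

    def lift(self, coords: np.ndarray) -> np.ndarray:
        """Map 2-D plane coordinates back to 3-D density space."""
        coords = np.asarray(coords, dtype=float)
        return (
            self.origin
            + coords[..., :1] * self.basis_u
            + coords[..., 1:] * self.basis_v
        )


def _roi_pixels(img: SkinImage, roi) -> np.ndarray:
    """Extract ROI pixels as an (n, 3) density array.

    ``roi`` is None (central 25% window), an ``(x, y, w, h)`` rectangle, or a
    boolean mask of the image shape.
    """
    d = img.density()
    if roi is None:
        h, w = img.height, img.width
        y0, y1 = h // 4, h // 4 + max(h // 2, 1)
        x0, x1 = w // 4, w // 4 + max(w // 2, 1)
        return d[y0:y1, x0:x1].reshape(-1, 3)
    roi_arr = np.asarray(roi)
    if roi_arr.dtype == bool:
        if roi_arr.shape != (img.height, img.width):
            raise ValueError("roi mask shape must match the image")
        return d[roi_arr]
    x, y, w, h = (int(v) for v in roi)
    if w <= 0 or h <= 0:
        raise ValueError("roi width and height must be positive")
    return d[y : y + h, x : x + w].reshape(-1, 3)


def estimate_color_plane(img: SkinImage, roi=None) -> ColorPlane:
    """PCA plane of the ROI densities (top-2 principal components).

    The ROI should be a small region with little illumination change; its
    pixels are assumed to lie on the pigment plane. Rejects ROIs with fewer
    than 16 pixels or with degenerate colour variation.
    """
    pix = _roi_pixels(img, roi)
    if pix.shape[0] < 16:
        raise ValueError(f"roi has {pix.shape[0]} pixels; need >= 16")
    origin = pix.mean(axis=0)
    centered = pix - origin
    # SVD of the centered cloud: principal directions and variances.
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    var = s**2 / pix.shape[0]
    if var[1] < 1e-12:
        raise ValueError(
            "roi colour variation is rank-deficient "
            f"(2nd principal variance {var[1]:.3e}); use a larger or more varied roi"
        )
    u, v = vt[0], vt[1]
    normal = np.cross(u, v)
    normal /= np.linalg.norm(normal)
    return ColorPlane(
        basis_u=u,
        basis_v=v,
        origin=origin,
        normal=normal,
        explained_variance=var / var.sum(),
    )


def remove_shading(
    img: SkinImage, plane: ColorPlane, illum: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Oblique projection along the illumination direction onto the plane.

    Solves, per pixel, the exact 3x3 system
    ``density = origin + u*basis_u + v*basis_v + s*illum`` and returns the
    in-plane coordinates ``(H, W, 2)`` and the density-space shading
    coefficient ``s`` with shape ``(H, W)``. This is *not* an orthogonal
    projection unless ``illum`` is parallel to the plane normal.
    """
    illum = np.asarray(illum, dtype=float)
    illum = illum / np.linalg.norm(illum)
    if abs(np.dot(plane.normal, illum)) <= 1e-6:
        raise ValueError(
            "illumination direction lies in the colour plane; "
            "shading removal is ill-posed"
        )
    m = np.column_stack([plane.basis_u, plane.basis_v, illum])
    sol = (img.density() - plane.origin) @ np.linalg.inv(m).T
    return sol[..., :2], sol[..., 2]


def _fastica_2d(
    x: np.ndarray,
    seed: int,
    max_iter: int = 500,
    tol: float = 1e-8,
    n_restarts: int = 3,
) -> np.ndarray:
    """Fixed-point ICA with tanh contrast and deflation, in 2-D.

    ``x`` is ``(n, 2)``. Returns the 2x2 mixing matrix ``A`` (columns are the
    source directions in the input coordinates, for the *centered* data).
    The fixed point is run from ``n_restarts`` seeded initialisations and the
    solution with the most non-Gaussian sources (summed |excess kurtosis|)
    wins — deterministic, and robust to the occasional bad starting point.
    """
    n = x.shape[0]
    mean = x.mean(axis=0)
    xc = x - mean
    cov = xc.T @ xc / n
    evals, evecs = np.linalg.eigh(cov)
    if evals[0] < 1e-15:
        raise ValueError("plane coordinates are degenerate; ICA needs 2-D variation")
    whiten = evecs @ np.diag(evals**-0.5) @ evecs.T  # symmetric whitening
    z = xc @ whiten.T

    kurt = np.mean(z**4, axis=0) - 3.0
    if np.all(np.abs(kurt) < 0.05):
        warnings.warn(
            "plane coordinates look near-Gaussian; ICA directions may be unstable",
            stacklevel=2,
        )

    rng = np.random.default_rng(seed)
    best: tuple[float, np.ndarray] | None = None
    last_error: ConvergenceError | None = None
    for restart in range(n_restarts):
        # First attempt starts at the global maximum of the 1-D contrast
        # landscape (the plane makes the search space a single angle);
        # later restarts use seeded random directions.
        init = _contrast_scan(z) if restart == 0 else None
        try:
            w_mat = _deflation(z, rng, max_iter, tol, init=init)
        except ConvergenceError as exc:
            last_error = exc
            continue
        sources = z @ w_mat.T
        score = float(np.abs(np.mean(sources**4, axis=0) - 3.0).sum())
        if best is None or score > best[0]:
            best = (score, w_mat)
    if best is None:
        raise last_error if last_error is not None else ConvergenceError(
            "ICA failed on every restart"
        )
    # x_c = A s with s = W z: mixing columns in input coordinates.
    return np.linalg.inv(whiten) @ best[1].T


_LOGCOSH_GAUSS = 0.3745672966146246  # E[log cosh nu], nu ~ N(0,1)


def _contrast_scan(z: np.ndarray, n_angles: int = 180) -> np.ndarray:
    """Direction of maximal log-cosh negentropy proxy over an angle grid."""
    thetas = np.linspace(0.0, np.pi, n_angles, endpoint=False)
    w = np.stack([np.cos(thetas), np.sin(thetas)])
    j = (np.log(np.cosh(z @ w)).mean(axis=0) - _LOGCOSH_GAUSS) ** 2
    t = thetas[int(np.argmax(j))]
    return np.array([np.cos(t), np.sin(t)])


def _deflation(
    z: np.ndarray,
    rng: np.random.Generator,
    max_iter: int,
    tol: float,
    init: np.ndarray | None = None,
) -> np.ndarray:
    """One deflation pass over whitened data; returns the 2x2 unmixing rows.

    Uses the stabilised form of the fixed-point update: a Newton step with
    step size ``mu`` that is reduced whenever the iteration stops
    contracting, which suppresses the period-2 oscillation the plain update
    (``mu = 1``) can fall into.
    """
    w_rows: list[np.ndarray] = []
    for comp in range(2):
        if comp == 0 and init is not None:
            w = init.copy()
        else:
            w = rng.normal(size=2)
        w /= np.linalg.norm(w)
        converged = False
        delta_prev = np.inf
        mu = 1.0
        for _ in range(max_iter):
            wz = z @ w
            g = np.tanh(wz)
            g_prime = 1.0 - g**2
            if mu >= 1.0:
                w_new = (z * g[:, None]).mean(axis=0) - g_prime.mean() * w
            else:
                beta = float((wz * g).mean())
                denom = g_prime.mean() - beta
                if abs(denom) < 1e-12:
                    denom = np.sign(denom) * 1e-12 if denom else 1e-12
                w_new = w - mu * ((z * g[:, None]).mean(axis=0) - beta * w) / denom
            for prev in w_rows:  # deflation: stay orthogonal to found rows
                w_new -= np.dot(w_new, prev) * prev
            norm = np.linalg.norm(w_new)
            if norm < 1e-12:
                w_new = rng.normal(size=2)
                for prev in w_rows:
                    w_new -= np.dot(w_new, prev) * prev
                norm = np.linalg.norm(w_new)
            w_new /= norm
            delta = abs(abs(np.dot(w_new, w)) - 1.0)
            if delta >= delta_prev and delta > tol:
                mu = max(mu * 0.5, 1 / 64)  # oscillating: damp the step
            delta_prev = delta
            w = w_new
            if delta < tol:
                converged = True
                break
        if not converged:
            raise ConvergenceError(
                f"ICA component {comp} did not converge after {max_iter} "
                f"iterations (last delta {delta:.3e})"
            )
        w_rows.append(w)
    return np.vstack(w_rows)


def estimate_pigment_vectors(
    plane_coords: np.ndarray,
    plane: ColorPlane,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-8,
    bias_percentile: float = 0.0,
    illum: np.ndarray | None = None,
) -> PigmentBasis:
    """Estimate the pigment basis by ICA in the 2-D plane coordinates.

    The recovered in-plane mixing directions are lifted to 3-D density space
    and normalised. ICA's inherent ambiguities are resolved deterministically:

    * sign — flipped so that at least half the pixels get a non-negative
      concentration on each axis;
    * order — the lifted vector with the larger G-to-R density ratio is
      labelled hemoglobin (hemoglobin absorbs green strongly); the other is
      melanin.

    The bias point is placed at the ``bias_percentile`` (default: minimum) of
    the data along each pigment axis, so concentrations are floored at zero.
    """
    coords = np.asarray(plane_coords, dtype=float).reshape(-1, 2)
    if coords.shape[0] < 100:
        raise ValueError(f"need >= 100 samples for ICA, got {coords.shape[0]}")
    mixing = _fastica_2d(coords, seed=seed, max_iter=max_iter, tol=tol)

    lifted = np.stack(
        [
            mixing[0, j] * plane.basis_u + mixing[1, j] * plane.basis_v
            for j in range(2)
        ],
        axis=1,
    )  # 3 x 2, columns are density-space pigment directions
    # Sign rule: pigments absorb, so each density direction must point toward
    # darkening (positive component sum). With the min-based bias floor this
    # also leaves every pixel's floored concentration non-negative.
    for j in range(2):
        if lifted[:, j].sum() < 0:
            lifted[:, j] = -lifted[:, j]
            mixing[:, j] = -mixing[:, j]

    # Concentrations of *all* pixels (origin-relative, before bias flooring).
    conc = coords @ np.linalg.inv(mixing).T
    # Normalise each direction; fold the scale into the concentrations.
    norms = np.linalg.norm(lifted, axis=0)
    lifted /= norms
    mixing /= norms
    conc *= norms

    ratio = lifted[1] / np.maximum(lifted[0], 1e-12)  # G/R per column
    hem_col = int(np.argmax(ratio))
    mel_col = 1 - hem_col

    floor = np.percentile(conc, bias_percentile, axis=0)
    bias_plane = mixing @ floor  # in-plane coords of the bias point
    bias3 = plane.lift(bias_plane)

    return PigmentBasis(
        melanin_vector=np.clip(lifted[:, mel_col], 0.0, None),
        hemoglobin_vector=np.clip(lifted[:, hem_col], 0.0, None),
        illumination_direction=(
            np.ones(3) / np.sqrt(3.0) if illum is None else illum
        ),
        bias=bias3,
    )


def project_concentrations(
    plane_coords: np.ndarray,
    shading: np.ndarray,
    basis: PigmentBasis,
    plane: ColorPlane,
) -> ConcentrationMap:
    """Convert plane coordinates to melanin/hemoglobin concentrations.

    Solves, per pixel, the 2x2 system expressing the bias-subtracted plane
    coordinate as ``mel * w_m + hem * w_h`` where ``w_m``/``w_h`` are the
    pigment vectors' in-plane coordinates. The shading field passes through
    unchanged. Negative concentrations are kept (diagnostic value).
    """
    w_m = np.array(
        [basis.melanin_vector @ plane.basis_u, basis.melanin_vector @ plane.basis_v]
    )
    w_h = np.array(
        [
            basis.hemoglobin_vector @ plane.basis_u,
            basis.hemoglobin_vector @ plane.basis_v,
        ]
    )
    a = np.column_stack([w_m, w_h])
    cond = np.linalg.cond(a)
    if cond > 1e8:
        raise ValueError(
            f"pigment vectors are near-parallel in the plane (cond {cond:.3e})"
        )
    rel = basis.bias - plane.origin
    bias2 = np.array([rel @ plane.basis_u, rel @ plane.basis_v])
    conc = (np.asarray(plane_coords) - bias2) @ np.linalg.inv(a).T
    return ConcentrationMap(
        melanin=conc[..., 0], hemoglobin=conc[..., 1], shading=np.asarray(shading)
    )


def plane_from_basis(basis: PigmentBasis) -> ColorPlane:
    """Exact colour plane spanned by a known pigment basis (origin at bias)."""
    u = basis.melanin_vector / np.linalg.norm(basis.melanin_vector)
    v = basis.hemoglobin_vector - np.dot(basis.hemoglobin_vector, u) * u
    v /= np.linalg.norm(v)
    normal = np.cross(u, v)
    normal /= np.linalg.norm(normal)
    return ColorPlane(basis_u=u, basis_v=v, origin=basis.bias.copy(), normal=normal)


def recover_with_basis(img: SkinImage, basis: PigmentBasis) -> ConcentrationMap:
    """Analytic inverse of the forward model for a *known* basis (no ICA).

    Builds the exact plane from the basis, removes shading by oblique
    projection and solves for the concentrations. On noiseless renders this
    reproduces the generating maps to machine precision wherever no
    reflectance clamping occurred.
    """
    plane = plane_from_basis(basis)
    coords, s_density = remove_shading(img, plane, basis.illumination_direction)
    # Density-space coefficient s corresponds to log-intensity offset -s.
    return project_concentrations(coords, -s_density, basis, plane)


def separate(
    img: SkinImage,
    roi=None,
    illum: np.ndarray | None = None,
    seed: int = 0,
) -> tuple[ConcentrationMap, PigmentBasis]:
    """Full pigment separation of an RGB skin image.

    Composes plane estimation (PCA on the ROI), shading removal (oblique
    projection), pigment-axis estimation (2-D ICA over the whole image) and
    concentration projection. Returns the concentration map (shading stored as
    log-intensity offset, positive = brighter) and the estimated basis.
    """
    if illum is None:
        illum = np.ones(3) / np.sqrt(3.0)
    plane = estimate_color_plane(img, roi)
    coords, s_density = remove_shading(img, plane, illum)
    basis = estimate_pigment_vectors(
        coords.reshape(-1, 2), plane, seed=seed, illum=illum
    )
    conc = project_concentrations(coords, -s_density, basis, plane)
    return conc, basis
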