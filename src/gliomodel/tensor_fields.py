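"""Synthetic diffusion-tensor fields and the tissue quantities derived from them.

This module is the "environment" half of the model: it builds brain-like
fields of water-diffusion tensors (standing in for DTI acquisitions), and
computes every macroscopic coefficient the glioma model extracts from them —
fractional anisotropy, the tissue volume fraction ``A(x)`` and its gradient,
the fibre orientation distribution function (ODF) on the unit circle, its
moments, the macroscopic tumour diffusion tensor ``D_T``, the associated
drift ``P_T = div(D_T)``, the integrin-binding steady state, and the
haptotaxis coefficient ``l(A)``.

Conventions
-----------
Tensors are stored as 3x3 symmetric positive-definite matrices per grid node
(water diffusivity, relative scale); the model runs on a 2D slice, so every
angular quantity uses the in-plane 2x2 block ``D2``.  The slice ODF is the
dimensional analogue of the 3D orientation distribution function,

    q(x, v̂) = 1 / (2 pi sqrt(det D2) (v̂ᵀ D2⁻¹ v̂)),

which is exactly normalised over the circle and equals the angular law of a
centred Gaussian with covariance ``D2`` — a property the test-suite uses as
an independent sampling oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Tuple

import numpy as np

__all__ = [
    "DiffusionTensorField",
    "TissueEnvironment",
    "OdfModel",
    "make_synthetic_dti",
    "make_brain_slice_field",
    "fractional_anisotropy",
    "odf_value",
    "odf_moments",
    "tumour_diffusion_tensor",
    "drift_vector",
    "integrin_steady_state",
    "integrin_sensitivity",
    "haptotaxis_coefficient",
    "haptotactic_velocity",
    "environment_from_field",
    "DEFAULT_K_PLUS",
    "DEFAULT_K_MINUS",
]

#: Integrin attachment/detachment rates (s^-1).  The receptor-binding
#: literature this model family builds on uses values of this magnitude;
#: they are defaults, not fitted quantities.
DEFAULT_K_PLUS = 0.034
DEFAULT_K_MINUS = 0.01

_SYNTHETIC_KINDS = ("isotropic", "single_bundle", "crossing", "ring", "layered")


@dataclass
class DiffusionTensorField:
    """A 2D grid of 3x3 water-diffusion tensors with a tissue mask.

    Parameters
    ----------
    origin : (2,) array-like
        Physical coordinate (mm) of node ``[0, 0]``, ordered ``(x, y)``.
    spacing : (2,) array-like
        Grid spacing (mm) per axis, ordered ``(dx, dy)``; must be positive.
    tensors : ndarray, shape (ny, nx, 3, 3)
        Symmetric positive-definite tensor per node (masked nodes).
    mask : ndarray of bool, shape (ny, nx)
        Inside-tissue indicator; must be non-empty.
    """

    origin: np.ndarray
    spacing: np.ndarray
    tensors: np.ndarray
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        self.spacing = np.asarray(self.spacing, dtype=float)
        self.tensors = np.asarray(self.tensors, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        self.validate()

    # -- invariants ---------------------------------------------------------
    def validate(self) -> None:
        if self.spacing.shape != (2,) or np.any(self.spacing <= 0):
            raise ValueError("grid spacing must be two positive lengths")
        if self.tensors.ndim != 4 or self.tensors.shape[2:] != (3, 3):
            raise ValueError("tensors must have shape (ny, nx, 3, 3)")
        if self.mask.shape != self.tensors.shape[:2]:
            raise ValueError("mask shape does not match tensor grid")
        if not self.mask.any():
            raise ValueError("mask is empty")
        t = self.tensors[self.mask]
        asym = np.abs(t - np.swapaxes(t, -1, -2)).max()
        if asym > 1e-12:
            raise ValueError(f"tensors not symmetric (max asymmetry {asym:g})")
        smallest = np.linalg.eigvalsh(t)[:, 0].min()
        if smallest <= 0:
            raise ValueError("tensors must be positive definite on the mask")

    # -- geometry helpers ---------------------------------------------------
    @property
    def shape(self) -> Tuple[int, int]:
        return self.mask.shape

    @property
    def x(self) -> np.ndarray:
        """Node x-coordinates (mm)."""
        return self.origin[0] + self.spacing[0] * np.arange(self.shape[1])

    @property
    def y(self) -> np.ndarray:
        """Node y-coordinates (mm)."""
        return self.origin[1] + self.spacing[1] * np.arange(self.shape[0])

    def inplane(self) -> np.ndarray:
        """In-plane 2x2 tensor block, shape (ny, nx, 2, 2)."""
        return self.tensors[..., :2, :2]


@dataclass
class TissueEnvironment:
    """Macroscopic tissue volume fraction and integrin kinetics on a grid.

    ``A`` is dimensionless in ``[0, 1)`` on masked nodes (0 outside the
    mask), ``grad_A`` is its spatial gradient in mm^-1 (0 outside), and
    ``k_plus``/``k_minus`` are the integrin attachment/detachment rates in
    s^-1.
    """

    A: np.ndarray
    grad_A: np.ndarray
    k_plus: float
    k_minus: float
    origin: np.ndarray = dc_field(default=None)  # type: ignore[assignment]
    spacing: np.ndarray = dc_field(default=None)  # type: ignore[assignment]
    mask: np.ndarray = dc_field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float)
        self.grad_A = np.asarray(self.grad_A, dtype=float)
        if self.k_plus <= 0 or self.k_minus <= 0:
            raise ValueError("binding rates k_plus, k_minus must be positive")
        if self.mask is not None:
            a = self.A[self.mask]
            if a.size and (a.min() < 0 or a.max() >= 1):
                raise ValueError("A must lie in [0, 1) on masked nodes")
        if not np.isfinite(self.grad_A).all():
            raise ValueError("grad_A must be finite")


def _central_gradient_masked(
    f: np.ndarray, spacing: np.ndarray, mask: np.ndarray
) -> np.ndarray:
    """Gradient of a masked nodal field: central differences inside, one-sided
    at mask boundaries, zero outside the mask.  Returns shape (ny, nx, 2) with
    components ordered (d/dx, d/dy)."""
    ny, nx = f.shape
    grad = np.zeros((ny, nx, 2))
    # axis 1 is x, axis 0 is y
    for axis, comp, h in ((1, 0, spacing[0]), (0, 1, spacing[1])):
        fwd_ok = np.zeros_like(mask)
        bwd_ok = np.zeros_like(mask)
        sl_in = [slice(None)] * 2
        sl_out = [slice(None)] * 2
        sl_in[axis] = slice(None, -1)
        sl_out[axis] = slice(1, None)
        fwd_ok[tuple(sl_in)] = mask[tuple(sl_out)]
        bwd_ok[tuple(sl_out)] = mask[tuple(sl_in)]
        f_fwd = np.zeros_like(f)
        f_bwd = np.zeros_like(f)
        f_fwd[tuple(sl_in)] = f[tuple(sl_out)]
        f_bwd[tuple(sl_out)] = f[tuple(sl_in)]
        both = mask & fwd_ok & bwd_ok
        only_f = mask & fwd_ok & ~bwd_ok
        only_b = mask & ~fwd_ok & bwd_ok
        g = np.zeros_like(f)
        g[both] = (f_fwd[both] - f_bwd[both]) / (2 * h)
        g[only_f] = (f_fwd[only_f] - f[only_f]) / h
        g[only_b] = (f[only_b] - f_bwd[only_b]) / h
        isolated = mask & ~fwd_ok & ~bwd_ok
        # isolated along this axis: derivative taken as zero; a fully isolated
        # node (no neighbours on either axis) is rejected by drift_vector.
        g[isolated] = 0.0
        grad[..., comp] = g
    return grad


# ---------------------------------------------------------------------------
# synthetic field catalogue
# ---------------------------------------------------------------------------

def _tensor_from_angle(theta, ratio, out_of_plane="min", scale=1e-3):
    """3x3 tensor whose in-plane leading eigenvector is (cos t, sin t) with
    in-plane eigenvalue ratio ``ratio``; out-of-plane eigenvalue equals the
    smaller in-plane one.  ``theta`` and ``ratio`` broadcast."""
    theta = np.asarray(theta, dtype=float)
    ratio = np.broadcast_to(np.asarray(ratio, dtype=float), theta.shape)
    c, s = np.cos(theta), np.sin(theta)
    lam1 = ratio * scale
    lam2 = np.full_like(lam1, scale)
    D = np.zeros(theta.shape + (3, 3))
    D[..., 0, 0] = lam1 * c * c + lam2 * s * s
    D[..., 1, 1] = lam1 * s * s + lam2 * c * c
    D[..., 0, 1] = D[..., 1, 0] = (lam1 - lam2) * c * s
    D[..., 2, 2] = lam2
    return D


def make_synthetic_dti(
    kind: str,
    shape: Tuple[int, int] = (64, 64),
    spacing: float | Tuple[float, float] = 1.0,
    anisotropy_ratio: float = 9.0,
    seed: int = 0,
    origin: Tuple[float, float] = (0.0, 0.0),
) -> DiffusionTensorField:
    """Generate a synthetic diffusion-tensor field with prescribed geometry.

    ``kind`` selects the fibre architecture:

    - ``isotropic``      — identity tensors everywhere (FA = 0);
    - ``single_bundle``  — a horizontal band of aligned fibres;
    - ``crossing``       — two orthogonal bands whose overlap mixes them;
    - ``ring``           — an annular bundle with tangential fibres;
    - ``layered``        — anisotropy ratio grading from 1 (bottom) to
      ``anisotropy_ratio`` (top), fibres horizontal.

    The output is deterministic for a given ``seed``; the tensors satisfy
    every :class:`DiffusionTensorField` invariant by construction.
    """
    if kind not in _SYNTHETIC_KINDS:
        raise ValueError(f"unknown kind {kind!r}; expected one of {_SYNTHETIC_KINDS}")
    spacing = np.broadcast_to(np.asarray(spacing, dtype=float), (2,)).copy()
    if np.any(spacing <= 0):
        raise ValueError("spacing must be positive")
    ny, nx = shape
    if ny < 8 or nx < 8:
        raise ValueError("shape must be at least 8x8")
    if anisotropy_ratio < 1:
        raise ValueError("anisotropy_ratio must be >= 1")
    scale = 1e-3  # mm^2/s, typical white-matter diffusivity magnitude
    x = origin[0] + spacing[0] * np.arange(nx)
    y = origin[1] + spacing[1] * np.arange(ny)
    X, Y = np.meshgrid(x, y)
    mask = np.ones((ny, nx), dtype=bool)
    iso = np.zeros((ny, nx, 3, 3))
    iso[..., 0, 0] = iso[..., 1, 1] = iso[..., 2, 2] = scale

    if kind == "isotropic":
        tensors = iso
    elif kind == "single_bundle":
        yc = 0.5 * (y[0] + y[-1])
        width = 0.2 * (y[-1] - y[0])
        band = np.abs(Y - yc) <= width / 2
        tensors = iso.copy()
        tensors[band] = _tensor_from_angle(0.0, anisotropy_ratio, scale=scale)
    elif kind == "crossing":
        yc = 0.5 * (y[0] + y[-1])
        xc = 0.5 * (x[0] + x[-1])
        wy = 0.2 * (y[-1] - y[0])
        wx = 0.2 * (x[-1] - x[0])
        hband = np.abs(Y - yc) <= wy / 2
        vband = np.abs(X - xc) <= wx / 2
        th = _tensor_from_angle(0.0, anisotropy_ratio, scale=scale)
        tv = _tensor_from_angle(np.pi / 2, anisotropy_ratio, scale=scale)
        tensors = iso.copy()
        tensors[hband] = th
        tensors[vband] = tv
        tensors[hband & vband] = 0.5 * (th + tv)  # crossing-fibre (planar) mix
    elif kind == "ring":
        xc, yc = 0.5 * (x[0] + x[-1]), 0.5 * (y[0] + y[-1])
        R = 0.3 * min(x[-1] - x[0], y[-1] - y[0])
        width = 0.4 * R
        r = np.hypot(X - xc, Y - yc)
        annulus = np.abs(r - R) <= width / 2
        theta_t = np.arctan2(Y - yc, X - xc) + np.pi / 2  # tangential
        tensors = iso.copy()
        tensors[annulus] = _tensor_from_angle(
            theta_t[annulus], anisotropy_ratio, scale=scale
        )
    else:  # layered
        frac = (Y - y[0]) / max(y[-1] - y[0], np.finfo(float).tiny)
        ratio = 1.0 + (anisotropy_ratio - 1.0) * frac
        tensors = _tensor_from_angle(np.zeros_like(Y), ratio, scale=scale)

    return DiffusionTensorField(
        origin=np.asarray(origin, float), spacing=spacing, tensors=tensors, mask=mask
    )


def _ratio_for_fa(fa):
    """In-plane eigenvalue ratio giving a prescribed FA for eigenvalues
    (ratio, 1, 1): the exact inversion of the three-eigenvalue FA formula."""
    fa = np.asarray(fa, dtype=float)
    return (1.0 + fa * np.sqrt(3.0 - 2.0 * fa**2)) / (1.0 - fa**2)


def make_brain_slice_field(
    shape: Tuple[int, int] = (96, 96),
    spacing: float = 0.5,
    anisotropy_ratio: float = 9.0,
    seed: int = 0,
    origin: Tuple[float, float] = (-59.0, -65.0),
) -> DiffusionTensorField:
    """A brain-slice-like synthetic scenario.

    An elliptical tissue mask; a moderately anisotropic background
    (fractional anisotropy smoothly varying in roughly [0.2, 0.45], with a
    smoothly rotating random fibre orientation — parenchyma is nowhere
    water-isotropic); an annular arc of strongly aligned tangential fibres
    (a corpus-callosum-like structure, FA near 0.85 at its crest); and a
    vertical para-midline bundle.  Structured bundles have smooth Gaussian
    cross-profiles, blended with the background in tensor space, so the
    tissue fraction A = FA and its gradient are smooth — the feature a
    fractional-anisotropy map of a real slice shows at imaging resolution.

    The default origin places the coordinate (-35, -41) mm (the model's
    default tumour seed) at the domain centre, inside moderate tissue and
    ~13 mm away from the arc.
    """
    from scipy.ndimage import gaussian_filter

    rng = np.random.default_rng(seed)
    spacing2 = np.array([spacing, spacing], dtype=float)
    ny, nx = shape
    scale = 1e-3
    x = origin[0] + spacing * np.arange(nx)
    y = origin[1] + spacing * np.arange(ny)
    X, Y = np.meshgrid(x, y)
    xc, yc = 0.5 * (x[0] + x[-1]), 0.5 * (y[0] + y[-1])
    ax_x, ax_y = 0.46 * (x[-1] - x[0]), 0.42 * (y[-1] - y[0])
    mask = ((X - xc) / ax_x) ** 2 + ((Y - yc) / ax_y) ** 2 <= 1.0

    # smoothly rotating random background orientation, moderate anisotropy
    noise_c = gaussian_filter(rng.standard_normal((ny, nx)), 8.0)
    noise_s = gaussian_filter(rng.standard_normal((ny, nx)), 8.0)
    theta_bg = 0.5 * np.arctan2(noise_s, noise_c)
    fa_noise = gaussian_filter(rng.standard_normal((ny, nx)), 10.0)
    span = max(fa_noise.max() - fa_noise.min(), 1e-12)
    fa_bg = 0.2 + 0.25 * (fa_noise - fa_noise.min()) / span
    T_bg = _tensor_from_angle(theta_bg, _ratio_for_fa(fa_bg), scale=scale)

    fa_max = min((anisotropy_ratio - 1.0) / np.sqrt(anisotropy_ratio**2 + 2.0), 0.95)

    # annular fibre arc with a smooth Gaussian cross-profile
    R = 0.28 * min(x[-1] - x[0], y[-1] - y[0])
    w_arc = 3.0 * spacing
    r = np.hypot(X - xc, Y - yc)
    u_arc = np.exp(-((r - R) ** 2) / (2 * w_arc**2))
    theta_t = np.arctan2(Y - yc, X - xc) + np.pi / 2
    T_arc = _tensor_from_angle(theta_t, _ratio_for_fa(fa_max), scale=scale)

    # vertical bundle, left of the arc (well away from the domain centre)
    xb = xc - 0.62 * ax_x
    w_vb = 4.0 * spacing
    u_vb = np.exp(-((X - xb) ** 2) / (2 * w_vb**2)) * np.exp(
        -((Y - yc) ** 2) / (2 * (0.7 * ax_y) ** 2)
    )
    T_vb = _tensor_from_angle(np.pi / 2, _ratio_for_fa(0.8 * fa_max), scale=scale)

    w1 = u_arc
    w2 = u_vb * (1.0 - u_arc)
    w0 = 1.0 - w1 - w2
    tensors = (
        w0[..., None, None] * T_bg
        + w1[..., None, None] * T_arc
        + w2[..., None, None] * T_vb
    )

    return DiffusionTensorField(
        origin=np.asarray(origin, float), spacing=spacing2, tensors=tensors, mask=mask
    )


# ---------------------------------------------------------------------------
# scalar tissue quantities
# ---------------------------------------------------------------------------

def fractional_anisotropy(D: np.ndarray) -> np.ndarray:
    """Fractional anisotropy of one or many 3x3 diffusion tensors.

    FA = sqrt(3/2) * ||lambda - mean(lambda)|| / ||lambda|| with ``lambda``
    the eigenvalues; lies in [0, 1], is invariant under rotation and positive
    scaling, and is undefined (raises) for a zero tensor.
    """
    D = np.asarray(D, dtype=float)
    lam = np.linalg.eigvalsh(D)
    norm = np.linalg.norm(lam, axis=-1)
    if np.any(norm == 0):
        raise ValueError("fractional anisotropy of the zero tensor is undefined")
    dev = lam - lam.mean(axis=-1, keepdims=True)
    fa = np.sqrt(1.5) * np.linalg.norm(dev, axis=-1) / norm
    return np.clip(fa, 0.0, 1.0)


def integrin_steady_state(A, k_plus: float, k_minus: float):
    """Steady bound-integrin fraction y* = k⁺A / (k⁺A + k⁻), in [0, 1)."""
    if k_plus <= 0 and k_minus <= 0:
        raise ValueError("at least one of k_plus, k_minus must be positive")
    A = np.asarray(A, dtype=float)
    return k_plus * A / (k_plus * A + k_minus)


def integrin_sensitivity(A, k_plus: float, k_minus: float):
    """f'(A) = k⁺k⁻ / (k⁺A + k⁻)², the derivative of the steady state."""
    A = np.asarray(A, dtype=float)
    return k_plus * k_minus / (k_plus * A + k_minus) ** 2


def haptotaxis_coefficient(A, params):
    """Subcellular-scale haptotaxis coefficient

    l(A) = λ1 f'(A) / (λ0 + A k⁺ + k⁻).

    ``params`` is a :class:`~gliomodel.pdifmp.ModelParams` (or anything with
    ``lambda0``, ``lambda1``, ``k_plus``, ``k_minus``).  Identically zero
    when λ1 = 0; its sign is the sign of λ1.
    """
    A = np.asarray(A, dtype=float)
    fp = integrin_sensitivity(A, params.k_plus, params.k_minus)
    return params.lambda1 * fp / (params.lambda0 + A * params.k_plus + params.k_minus)


def haptotactic_velocity(l: np.ndarray, D_T: np.ndarray, grad_A: np.ndarray) -> np.ndarray:
    """Haptotactic drift h(x) = l(A(x)) · D_T(x) · ∇A(x), per node."""
    l = np.asarray(l, float)
    D_T = np.asarray(D_T, float)
    grad_A = np.asarray(grad_A, float)
    if D_T.shape[:-2] != grad_A.shape[:-1] or D_T.shape[:-2] != l.shape:
        raise ValueError("l, D_T and grad_A must be co-registered")
    return l[..., None] * np.einsum("...ij,...j->...i", D_T, grad_A)


def environment_from_field(
    field: DiffusionTensorField,
    k_plus: float = DEFAULT_K_PLUS,
    k_minus: float = DEFAULT_K_MINUS,
) -> TissueEnvironment:
    """Tissue environment with A(x) = FA(D(x)) on the mask, 0 outside.

    The gradient uses central differences inside the mask and one-sided
    stencils at the mask boundary.
    """
    A = np.zeros(field.shape)
    A[field.mask] = fractional_anisotropy(field.tensors[field.mask])
    A = np.clip(A, 0.0, 1.0 - 1e-9)
    A[~field.mask] = 0.0
    grad = _central_gradient_masked(A, field.spacing, field.mask)
    return TissueEnvironment(
        A=A,
        grad_A=grad,
        k_plus=k_plus,
        k_minus=k_minus,
        origin=field.origin,
        spacing=field.spacing,
        mask=field.mask,
    )


# ---------------------------------------------------------------------------
# orientation distribution function
# ---------------------------------------------------------------------------

class OdfModel:
    """Fibre orientation distribution derived from a tensor field.

    Wraps a :class:`DiffusionTensorField` together with the cell speed
    ``alpha`` (mm/s).  The velocity space is the circle of radius ``alpha``;
    ``w = alpha**2`` is the bookkeeping normalisation constant of the jump
    kernel K = q / w.  Per-node quantities derived from the in-plane 2x2
    block are precomputed for fast evaluation and sampling.
    """

    def __init__(
        self,
        field: DiffusionTensorField,
        alpha: float,
        angular_resolution: int = 720,
    ) -> None:
        if alpha <= 0:
            raise ValueError("cell speed alpha must be positive")
        if angular_resolution < 8:
            raise ValueError("angular_resolution too small")
        self.field = field
        self.alpha = float(alpha)
        self.w = float(alpha) ** 2
        self.angular_resolution = int(angular_resolution)
        D2 = field.inplane()
        det = D2[..., 0, 0] * D2[..., 1, 1] - D2[..., 0, 1] * D2[..., 1, 0]
        self._det = det
        inv = np.empty_like(D2)
        with np.errstate(divide="ignore", invalid="ignore"):
            inv[..., 0, 0] = D2[..., 1, 1] / det
            inv[..., 1, 1] = D2[..., 0, 0] / det
            inv[..., 0, 1] = -D2[..., 0, 1] / det
            inv[..., 1, 0] = -D2[..., 1, 0] / det
        inv[~field.mask] = np.eye(2)
        self._det = np.where(field.mask, det, 1.0)
        self._inv = inv
        lam_max = np.linalg.eigvalsh(D2.reshape(-1, 2, 2))[:, 1].reshape(det.shape)
        # q is maximal along the leading eigenvector: v̂ᵀD⁻¹v̂ attains 1/lam_max
        self._qmax = lam_max / (2 * np.pi * np.sqrt(np.abs(self._det)))

    # angles of the default quadrature grid (uniform on [0, 2pi))
    @property
    def _angles(self) -> np.ndarray:
        return np.linspace(0.0, 2 * np.pi, self.angular_resolution, endpoint=False)

    def values_at(self, node: Tuple[int, int], directions: np.ndarray) -> np.ndarray:
        """ODF values at grid ``node`` for an array of unit directions."""
        directions = np.asarray(directions, dtype=float)
        inv = self._inv[node]
        quad = np.einsum("...i,ij,...j->...", directions, inv, directions)
        return 1.0 / (2 * np.pi * np.sqrt(self._det[node]) * quad)

    def qmax_at(self, node: Tuple[int, int]) -> float:
        return float(self._qmax[node])

    def second_moments(self) -> np.ndarray:
        """Direction second moment ∫ q(x, v̂) v̂⊗v̂ dv̂ per node, shape (ny, nx, 2, 2).

        Computed by the trapezoid rule on the uniform angular grid, which is
        spectrally accurate for these smooth periodic densities.
        """
        ang = self._angles
        v = np.stack([np.cos(ang), np.sin(ang)], axis=-1)  # (na, 2)
        # quadratic form per node and angle
        quad = np.einsum("ai,yxij,aj->yxa", v, self._inv, v)
        q = 1.0 / (2 * np.pi * np.sqrt(self._det)[..., None] * quad)
        outer = np.einsum("ai,aj->aij", v, v)
        dtheta = 2 * np.pi / self.angular_resolution
        return np.einsum("yxa,aij->yxij", q, outer) * dtheta

    def normalisation_at(self, node: Tuple[int, int]) -> float:
        """Numerically integrated ODF mass at a node (should be 1)."""
        ang = self._angles
        v = np.stack([np.cos(ang), np.sin(ang)], axis=-1)
        q = self.values_at(node, v)
        return float(q.sum() * 2 * np.pi / self.angular_resolution)


def odf_value(model: OdfModel, node: Tuple[int, int], direction) -> float:
    """ODF density at ``node`` in unit ``direction`` (strictly positive, even)."""
    direction = np.asarray(direction, dtype=float)
    if abs(np.linalg.norm(direction) - 1.0) > 1e-9:
        raise ValueError("direction must have unit norm")
    return float(model.values_at(node, direction))


def odf_moments(model: OdfModel, node: Tuple[int, int]) -> Tuple[np.ndarray, np.ndarray]:
    """Mean direction E_q and second moment V_q of the ODF at a node.

    Symmetry of the fibre distribution forces E_q = 0; V_q is symmetric
    positive definite with unit trace (directions are unit vectors).
    """
    ang = model._angles
    v = np.stack([np.cos(ang), np.sin(ang)], axis=-1)
    q = model.values_at(node, v)
    dtheta = 2 * np.pi / model.angular_resolution
    E = (q[:, None] * v).sum(axis=0) * dtheta
    V = np.einsum("a,ai,aj->ij", q, v - E, v - E) * dtheta
    return E, V


def tumour_diffusion_tensor(model: OdfModel, lambda0: float) -> np.ndarray:
    """Macroscopic tumour diffusion tensor per node, shape (ny, nx, 2, 2).

    D_T(x) = (alpha² / λ0) ∫ q(x, v̂) v̂⊗v̂ dv̂  (mm²/s); the velocity
    magnitude alpha factors out of the direction integral, so
    trace(D_T) = alpha²/λ0 at every node.  Entries scale as 1/λ0.
    """
    if lambda0 <= 0:
        raise ValueError("lambda0 must be positive")
    return (model.alpha**2 / lambda0) * model.second_moments()


def drift_vector(
    D_T: np.ndarray, spacing, mask: np.ndarray | None = None
) -> np.ndarray:
    """Componentwise divergence of the diffusion tensor, (P_T)_i = Σ_j ∂_j D_ij.

    This is the drift velocity of the myopic-diffusion flux
    ∇∇:(D_T M) = ∇·(D_T ∇M + (∇·D_T) M).  Central differences inside the
    mask, one-sided at the mask boundary; exactly zero for spatially
    constant fields.  Raises if the mask contains a node with no masked
    neighbour on either axis (no derivative can be formed).
    """
    D_T = np.asarray(D_T, dtype=float)
    spacing = np.broadcast_to(np.asarray(spacing, dtype=float), (2,))
    ny, nx = D_T.shape[:2]
    if mask is None:
        mask = np.ones((ny, nx), dtype=bool)
    # reject isolated nodes
    nb = np.zeros((ny, nx), dtype=int)
    nb[:, :-1] += mask[:, 1:]
    nb[:, 1:] += mask[:, :-1]
    nb[:-1, :] += mask[1:, :]
    nb[1:, :] += mask[:-1, :]
    if np.any(mask & (nb == 0)):
        raise ValueError("mask contains isolated nodes; divergence undefined")
    P = np.zeros((ny, nx, 2))
    for i in range(2):
        for j in range(2):
            g = _central_gradient_masked(D_T[..., i, j], spacing, mask)
            P[..., i] += g[..., j]
    return P
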