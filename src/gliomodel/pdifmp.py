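"""Microscale cell motion as a piecewise diffusion Markov process.

The state of one glioma cell is U_t = (X_t, Z_t, V_t):

- ``X_t`` — position (mm), driven between jumps by dX = V dt + sigma dW;
- ``Z_t`` — deviation of the bound-integrin fraction from its local steady
  state y* = k⁺A/(k⁺A + k⁻), relaxing along
  dz/dt = -[(k⁺A(x) + k⁻) z - f'(A(x)) <v, ∇A(x)>];
- ``V_t`` — velocity of constant magnitude alpha, piecewise constant, with
  reorientations at the jump times of an inhomogeneous Poisson process with
  state-dependent rate lambda(z) = lambda0 - lambda1 z (floored at 0) and
  post-jump directions drawn from the fibre orientation distribution q(x, ·).

Jump times are sampled by thinning against the global bound
lambda_bar = lambda0 + |lambda1| (valid because |z| < 1).  Between jumps the
position SDE has constant coefficients, so the Euler–Maruyama update is
exact for any step length; the internal variable uses an exact exponential
integrator with environment coefficients frozen per substep, so the substep
only needs to resolve the spatial variation of the tissue along the path.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np

from .tensor_fields import (
    DEFAULT_K_MINUS,
    DEFAULT_K_PLUS,
    OdfModel,
    TissueEnvironment,
)

__all__ = [
    "ModelParams",
    "MicroState",
    "MicroPath",
    "ConstantEnvironment",
    "FieldEnvironment",
    "jump_rate",
    "flow_segment",
    "sample_jump_time",
    "sample_new_velocity",
    "simulate_path",
    "simulate_ensemble",
    "ensemble_density",
]

logger = logging.getLogger(__name__)

DAY = 86400.0  # seconds


@dataclass(frozen=True)
class ModelParams:
    """All scalar model constants (SI units: s, mm, cells/mm^3).

    Defaults are the model's literature operating point: cell speed
    alpha = 0.21e-3 mm/s, basal turning rate lambda0 = 0.8 1/s,
    integrin-coupled turning weight lambda1 = 0.8 1/s, proliferation rate
    mu0 = 8.44e-7 1/s, carrying capacity K_M = 1e6 cells/mm^3, and the
    stochastic velocity amplitude sigma (studied over 0.01–0.2; the
    baseline parameter studies use sigma = 0).

    ``strict_turning`` enforces the sharp admissibility condition
    lambda0 - lambda1 z >= 0 over z in [y*_min - 1, y*_max] (``y_star_range``
    covers the field's attainable steady states).  Parameter sweeps probing
    outside the admissible band — as sensitivity studies routinely do —
    construct params with ``strict_turning=False``; the microscale jump rate
    floors at zero regardless.
    """

    lambda0: float = 0.8
    lambda1: float = 0.8
    k_plus: float = DEFAULT_K_PLUS
    k_minus: float = DEFAULT_K_MINUS
    alpha: float = 0.21e-3
    sigma: float = 0.0
    mu0: float = 8.44e-7
    K_M: float = 1.0e6
    strict_turning: bool = True
    y_star_range: Tuple[float, float] = (0.0, 1.0)

    def __post_init__(self) -> None:
        if self.lambda0 <= 0:
            raise ValueError("lambda0 must be positive")
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")
        if self.k_plus <= 0 or self.k_minus <= 0:
            raise ValueError("k_plus and k_minus must be positive")
        if self.mu0 < 0:
            raise ValueError("mu0 must be non-negative")
        if self.K_M <= 0:
            raise ValueError("K_M must be positive")
        if self.strict_turning:
            lo, hi = self.y_star_range
            # worst case of lambda0 - lambda1*z over z in [lo - 1, hi]
            worst = min(
                self.lambda0 - self.lambda1 * hi,
                self.lambda0 - self.lambda1 * (lo - 1.0),
            )
            if worst < 0:
                raise ValueError(
                    "inadmissible turning rate: lambda0 - lambda1*z < 0 for "
                    f"z in [{lo - 1.0:g}, {hi:g}] (lambda0={self.lambda0:g}, "
                    f"lambda1={self.lambda1:g}); construct with "
                    "strict_turning=False to probe outside the admissible band"
                )

    @property
    def lambda_bar(self) -> float:
        """Global hazard bound lambda0 + |lambda1| (|z| < 1)."""
        return self.lambda0 + abs(self.lambda1)


@dataclass
class MicroState:
    """Instantaneous cell state: position x (mm), integrin deviation z,
    velocity v with |v| = alpha (mm/s), time t (s)."""

    x: np.ndarray
    z: float
    v: np.ndarray
    t: float = 0.0

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        if not (np.isfinite(self.x).all() and np.isfinite(self.v).all() and math.isfinite(self.z)):
            raise ValueError("non-finite micro state")


@dataclass
class MicroPath:
    """One simulated trajectory.

    ``jump_times`` are the (strictly increasing) reorientation instants;
    the saved states are sampled on the requested save grid plus at every
    jump (velocity is càdlàg: the velocity stored at a jump time is the
    post-jump one).  Position is continuous across jumps.
    """

    jump_times: np.ndarray
    times: np.ndarray
    x: np.ndarray  # (n_saved, 2)
    z: np.ndarray
    v: np.ndarray  # (n_saved, 2)
    seed: Optional[int] = None

    @property
    def n_jumps(self) -> int:
        return len(self.jump_times)

    def position_at(self, t: float) -> np.ndarray:
        """Position at time t by linear interpolation of saved samples."""
        return np.array(
            [np.interp(t, self.times, self.x[:, 0]), np.interp(t, self.times, self.x[:, 1])]
        )


# ---------------------------------------------------------------------------
# environments
# ---------------------------------------------------------------------------

class ConstantEnvironment:
    """Spatially homogeneous tissue: constant A, ∇A and fibre tensor.

    ``tensor`` is the in-plane 2x2 diffusion tensor shaping the ODF (any
    SPD matrix; the ODF is scale-invariant).
    """

    def __init__(
        self,
        A: float = 0.3,
        grad_A: Sequence[float] = (0.0, 0.0),
        tensor: Optional[np.ndarray] = None,
        k_plus: float = DEFAULT_K_PLUS,
        k_minus: float = DEFAULT_K_MINUS,
    ) -> None:
        self.A0 = float(A)
        self.gradA0 = np.asarray(grad_A, dtype=float)
        self.k_plus = float(k_plus)
        self.k_minus = float(k_minus)
        D2 = np.eye(2) if tensor is None else np.asarray(tensor, dtype=float)
        self._set_tensor(D2)
        self.spacing_scale = math.inf  # no spatial structure to resolve

    def _set_tensor(self, D2: np.ndarray) -> None:
        det = float(np.linalg.det(D2))
        if det <= 0:
            raise ValueError("ODF tensor must be positive definite")
        self._inv = np.linalg.inv(D2)
        self._norm = 1.0 / (2 * np.pi * math.sqrt(det))
        lam_max = float(np.linalg.eigvalsh(D2)[-1])
        self._qmax = lam_max / (2 * np.pi * math.sqrt(det))

    def tissue(self, x0: float, x1: float) -> Tuple[float, float, float]:
        """(A, dA/dx, dA/dy) at a position."""
        return self.A0, self.gradA0[0], self.gradA0[1]

    def odf_params(self, x0: float, x1: float):
        """(inverse in-plane tensor, normalisation, sup q) at a position."""
        return self._inv, self._norm, self._qmax


class FieldEnvironment:
    """Gridded tissue: bilinear A and ∇A, nearest-masked-node ODF.

    Quantities outside the mask are extended by the nearest masked node
    (cells are free to leave the domain; the tissue they see saturates at
    the boundary values).
    """

    def __init__(self, env: TissueEnvironment, odf: OdfModel) -> None:
        if env.origin is None or env.spacing is None or env.mask is None:
            raise ValueError("TissueEnvironment must carry grid metadata")
        self.k_plus = env.k_plus
        self.k_minus = env.k_minus
        self.origin = np.asarray(env.origin, float)
        self.spacing = np.asarray(env.spacing, float)
        self.mask = env.mask
        self.spacing_scale = float(self.spacing.min())
        # nearest-masked-node extension of A and grad A
        from scipy.ndimage import distance_transform_edt

        ind = distance_transform_edt(
            ~env.mask, return_distances=False, return_indices=True
        )
        self._A = env.A[tuple(ind)]
        self._gA = env.grad_A[tuple(ind)]
        self._odf = odf
        self._ind = ind

    def _cell(self, x0: float, x1: float) -> Tuple[int, int]:
        ny, nx = self.mask.shape
        ix = int(round((x0 - self.origin[0]) / self.spacing[0]))
        iy = int(round((x1 - self.origin[1]) / self.spacing[1]))
        return min(max(iy, 0), ny - 1), min(max(ix, 0), nx - 1)

    def tissue(self, x0: float, x1: float) -> Tuple[float, float, float]:
        # bilinear interpolation of the extended fields
        ny, nx = self.mask.shape
        fx = (x0 - self.origin[0]) / self.spacing[0]
        fy = (x1 - self.origin[1]) / self.spacing[1]
        fx = min(max(fx, 0.0), nx - 1.0)
        fy = min(max(fy, 0.0), ny - 1.0)
        ix, iy = int(fx), int(fy)
        ix = min(ix, nx - 2) if nx > 1 else 0
        iy = min(iy, ny - 2) if ny > 1 else 0
        tx, ty = fx - ix, fy - iy
        A = self._A
        g = self._gA
        w00 = (1 - tx) * (1 - ty)
        w01 = tx * (1 - ty)
        w10 = (1 - tx) * ty
        w11 = tx * ty
        a = (
            w00 * A[iy, ix]
            + w01 * A[iy, ix + 1]
            + w10 * A[iy + 1, ix]
            + w11 * A[iy + 1, ix + 1]
        )
        gx = (
            w00 * g[iy, ix, 0]
            + w01 * g[iy, ix + 1, 0]
            + w10 * g[iy + 1, ix, 0]
            + w11 * g[iy + 1, ix + 1, 0]
        )
        gy = (
            w00 * g[iy, ix, 1]
            + w01 * g[iy, ix + 1, 1]
            + w10 * g[iy + 1, ix, 1]
            + w11 * g[iy + 1, ix + 1, 1]
        )
        return a, gx, gy

    def odf_params(self, x0: float, x1: float):
        iy, ix = self._cell(x0, x1)
        iy, ix = self._ind[0][iy, ix], self._ind[1][iy, ix]  # nearest masked
        node = (iy, ix)
        return self._odf._inv[node], 1.0 / (
            2 * np.pi * np.sqrt(self._odf._det[node])
        ), self._odf.qmax_at(node)


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------

_warned_negative_rate = False


def jump_rate(z: float, params: ModelParams) -> float:
    """Turning rate lambda(z) = lambda0 - lambda1*z, floored at zero.

    A transient numerical excursion of z outside its invariant interval can
    make the linear expression negative; the contract is to floor at 0 and
    log a warning once.
    """
    lam = params.lambda0 - params.lambda1 * z
    if lam < 0:
        global _warned_negative_rate
        if not _warned_negative_rate:
            logger.warning(
                "turning rate lambda0 - lambda1*z = %g < 0 (z=%g); flooring at 0",
                lam,
                z,
            )
            _warned_negative_rate = True
        return 0.0
    return lam


def _flow_step(x0, x1, z, v0, v1, dt, sqdt_sigma, env, params, rng):
    """One exact-in-x flow substep; returns updated (x0, x1, z)."""
    A, gx, gy = env.tissue(x0, x1)
    a = env.k_plus * A + env.k_minus
    fp = env.k_plus * env.k_minus / (a * a)  # f'(A) with the same denominator
    b = fp * (v0 * gx + v1 * gy)
    # exact relaxation of z' = -(a z - b) with frozen coefficients
    e = math.exp(-a * dt)
    z = (z - b / a) * e + b / a
    x0 += v0 * dt
    x1 += v1 * dt
    if sqdt_sigma:
        s = sqdt_sigma * math.sqrt(dt)
        x0 += s * rng.standard_normal()
        x1 += s * rng.standard_normal()
    return x0, x1, z


def _flow_dt(env, params: ModelParams) -> float:
    """Flow substep: resolve z relaxation forcing and tissue variation."""
    dt_z = 0.2 / (params.k_plus + params.k_minus)
    dt_x = 0.25 * env.spacing_scale / params.alpha
    return min(dt_z, dt_x)


def flow_segment(
    state: MicroState,
    dt: float,
    environment,
    rng: np.random.Generator,
    params: Optional[ModelParams] = None,
) -> MicroState:
    """Advance the continuous components over a jump-free interval of length dt.

    Position follows the Euler–Maruyama update of dX = v dt + sigma dW
    (exact here, since v and sigma are constant over the segment); z follows
    its linear relaxation ODE with tissue coefficients interpolated at the
    current position and frozen per substep.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    params = params or ModelParams()
    x0, x1 = float(state.x[0]), float(state.x[1])
    v0, v1 = float(state.v[0]), float(state.v[1])
    z = float(state.z)
    h = _flow_dt(environment, params)
    remaining = dt
    while remaining > 1e-15 * dt:
        step = min(h, remaining)
        x0, x1, z = _flow_step(
            x0, x1, z, v0, v1, step, params.sigma, environment, params, rng
        )
        remaining -= step
    return MicroState(
        x=np.array([x0, x1]), z=z, v=state.v.copy(), t=state.t + dt
    )


def sample_new_velocity(
    x: np.ndarray, model, rng: np.random.Generator, alpha: Optional[float] = None
) -> np.ndarray:
    """Draw a post-jump velocity from the local ODF; |v'| = alpha exactly.

    ``model`` may be an :class:`~gliomodel.tensor_fields.OdfModel` (the ODF
    of the nearest masked node is used) or an environment exposing
    ``odf_params``.  Sampling is rejection against the uniform circular
    proposal with the exact bound sup q.
    """
    x = np.asarray(x, dtype=float)
    if isinstance(model, OdfModel):
        env = _OdfAdapter(model)
        alpha = model.alpha if alpha is None else alpha
    else:
        env = model
        if alpha is None:
            raise ValueError("alpha required when sampling from an environment")
    inv, norm, qmax = env.odf_params(float(x[0]), float(x[1]))
    if not math.isfinite(qmax) or qmax <= 0:
        raise ValueError("invalid rejection bound for the ODF")
    i00, i01, i11 = inv[0, 0], inv[0, 1], inv[1, 1]
    while True:
        theta = rng.uniform(0.0, 2 * np.pi)
        c, s = math.cos(theta), math.sin(theta)
        quad = i00 * c * c + 2 * i01 * c * s + i11 * s * s
        if rng.uniform(0.0, qmax) * quad <= norm:
            return np.array([alpha * c, alpha * s])


class _OdfAdapter:
    """Expose an OdfModel through the environment sampling interface."""

    def __init__(self, odf: OdfModel) -> None:
        self._odf = odf
        from scipy.ndimage import distance_transform_edt

        self._ind = distance_transform_edt(
            ~odf.field.mask, return_distances=False, return_indices=True
        )

    def odf_params(self, x0: float, x1: float):
        f = self._odf.field
        ny, nx = f.mask.shape
        ix = min(max(int(round((x0 - f.origin[0]) / f.spacing[0])), 0), nx - 1)
        iy = min(max(int(round((x1 - f.origin[1]) / f.spacing[1])), 0), ny - 1)
        node = (self._ind[0][iy, ix], self._ind[1][iy, ix])
        return (
            self._odf._inv[node],
            1.0 / (2 * np.pi * np.sqrt(self._odf._det[node])),
            self._odf.qmax_at(node),
        )


def sample_jump_time(
    state: MicroState,
    environment,
    rng: np.random.Generator,
    params: Optional[ModelParams] = None,
) -> float:
    """Waiting time to the next reorientation, by thinning.

    Candidate times are exponential with the global bound
    lambda_bar = lambda0 + |lambda1|; each candidate is accepted with
    probability lambda(z at the candidate)/lambda_bar, with the continuous
    components advanced along the frozen-velocity flow in between.  The
    accepted time has exactly the survival law
    exp(-∫ lambda(z(s)) ds).
    """
    params = params or ModelParams()
    lam_bar = params.lambda_bar
    x0, x1 = float(state.x[0]), float(state.x[1])
    v0, v1 = float(state.v[0]), float(state.v[1])
    z = float(state.z)
    h = _flow_dt(environment, params)
    tau = 0.0
    while True:
        c = rng.exponential(1.0 / lam_bar)
        # advance flow by c in substeps
        remaining = c
        while remaining > 0:
            step = min(h, remaining)
            x0, x1, z = _flow_step(
                x0, x1, z, v0, v1, step, params.sigma, environment, params, rng
            )
            remaining -= step
        tau += c
        if rng.uniform() * lam_bar <= jump_rate(z, params):
            return tau


def simulate_path(
    u0: MicroState,
    T: float,
    params: ModelParams,
    environment,
    rng: np.random.Generator,
    save_times: Optional[Sequence[float]] = None,
    seed: Optional[int] = None,
) -> MicroPath:
    """Simulate one PDifMP trajectory on [0, T].

    Alternates jump-free flow segments with reorientation events: waiting
    times by thinning, post-jump velocities from the local ODF.  States are
    recorded at ``save_times`` (default: 101 uniform instants) and at every
    jump; position is continuous, velocity càdlàg.
    """
    if T <= 0:
        raise ValueError("T must be positive")
    if save_times is None:
        save_times = np.linspace(0.0, T, 101)
    save_times = np.asarray(save_times, dtype=float)

    lam_bar = params.lambda_bar
    h = _flow_dt(environment, params)
    x0, x1 = float(u0.x[0]), float(u0.x[1])
    v0, v1 = float(u0.v[0]), float(u0.v[1])
    z = float(u0.z)
    t = float(u0.t)

    jump_times: List[float] = []
    rec_t: List[float] = [t]
    rec_x: List[Tuple[float, float]] = [(x0, x1)]
    rec_z: List[float] = [z]
    rec_v: List[Tuple[float, float]] = [(v0, v1)]
    save_iter = iter(save_times[save_times > t])
    next_save = next(save_iter, None)

    def advance_to(target: float) -> None:
        """Flow (no jump) from t to target, recording crossed save points."""
        nonlocal x0, x1, z, t, next_save
        while t < target - 1e-15 * max(target, 1.0):
            stop = min(t + h, target)
            if next_save is not None and next_save <= stop:
                stop = next_save
            dt = stop - t
            if dt > 0:
                x0, x1, z = _flow_step(
                    x0, x1, z, v0, v1, dt, params.sigma, environment, params, rng
                )
                t = stop
            else:
                t = stop
            if next_save is not None and t >= next_save - 1e-15 * max(T, 1.0):
                rec_t.append(t)
                rec_x.append((x0, x1))
                rec_z.append(z)
                rec_v.append((v0, v1))
                next_save = next(save_iter, None)

    while t < T:
        c = rng.exponential(1.0 / lam_bar)
        if t + c >= T:
            advance_to(T)
            break
        advance_to(t + c)
        if rng.uniform() * lam_bar <= jump_rate(z, params):
            v = sample_new_velocity(
                np.array([x0, x1]), environment, rng, alpha=params.alpha
            )
            v0, v1 = float(v[0]), float(v[1])
            jump_times.append(t)
            rec_t.append(t)
            rec_x.append((x0, x1))
            rec_z.append(z)
            rec_v.append((v0, v1))

    return MicroPath(
        jump_times=np.asarray(jump_times),
        times=np.asarray(rec_t),
        x=np.asarray(rec_x),
        z=np.asarray(rec_z),
        v=np.asarray(rec_v),
        seed=seed,
    )


def simulate_ensemble(
    n: int,
    u0_sampler: Callable[[np.random.Generator], MicroState],
    T: float,
    params: ModelParams,
    environment,
    seed: int,
    save_times: Optional[Sequence[float]] = None,
) -> List[MicroPath]:
    """n independent trajectories via child RNG streams spawned from ``seed``.

    The master ``numpy.random.SeedSequence(seed)`` is split into one child
    per path, so the ensemble is reproducible (and order-independent under
    parallel execution).
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    children = np.random.SeedSequence(seed).spawn(n)
    paths = []
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        u0 = u0_sampler(rng)
        paths.append(
            simulate_path(u0, T, params, environment, rng, save_times, seed=i)
        )
    return paths


def ensemble_density(
    paths: Sequence[MicroPath],
    grid,
    t: float,
) -> Tuple[np.ndarray, int]:
    """Histogram of path positions at time t on a grid.

    ``grid`` is anything with ``origin``, ``spacing`` and ``shape``
    attributes (e.g. a :class:`~gliomodel.tensor_fields.DiffusionTensorField`
    or a :class:`~gliomodel.macro_pde.MacroCoefficients`); bins are the grid
    cells centred on the nodes.  Positions are linearly interpolated between
    saved samples.  Returns ``(counts, n_outside)`` with
    ``counts.sum() + n_outside == len(paths)``.
    """
    origin = np.asarray(grid.origin, float)
    spacing = np.broadcast_to(np.asarray(grid.spacing, float), (2,))
    ny, nx = grid.shape
    pos = np.array([p.position_at(t) for p in paths])
    ix = np.floor((pos[:, 0] - origin[0]) / spacing[0] + 0.5).astype(int)
    iy = np.floor((pos[:, 1] - origin[1]) / spacing[1] + 0.5).astype(int)
    inside = (ix >= 0) & (ix < nx) & (iy >= 0) & (iy < ny)
    counts = np.zeros((ny, nx))
    np.add.at(counts, (iy[inside], ix[inside]), 1.0)
    return counts, int((~inside).sum())
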