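"""Well-tempered metadynamics on analytic 1D/2D collective-variable
potentials, driven by overdamped Langevin dynamics.

The well-tempered scheme deposits Gaussian hills whose height decays with
the bias already present at the deposition point,
``h = h0 * exp(-V_bias(s)/(kB*dT))`` with ``dT = (gamma - 1) T``, so
revisited regions receive ever smaller corrections. The free-energy
profile is recovered from the accumulated bias as
``F(s) = -(gamma/(gamma-1)) * V_bias(s)``, shifted to zero at its minimum.
Overdamped (inertia-free) dynamics are the simplest dynamics with the
correct stationary distribution, which is all the toy engine needs.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ToyPotential", "BiasState", "double_well", "harmonic",
           "langevin_run", "deposit_hill", "reconstruct_fes"]

KB = 0.0019872041  # kcal/(mol*K)


@dataclass
class ToyPotential:
    """Analytic potential over a 1D or 2D collective variable."""
    value: callable               # V(s) -> kcal/mol
    gradient: callable            # dV/ds -> array like s
    bounds: tuple                 # ((lo, hi), ...) per dimension
    ndim: int = 1


def double_well(barrier: float = 3.0, half_width: float = 1.0) -> ToyPotential:
    """Symmetric 1D double well, minima at +-half_width, barrier at 0."""
    a = half_width

    def v(s):
        x = np.asarray(s, dtype=float)[..., 0]
        return barrier * ((x / a) ** 2 - 1.0) ** 2

    def g(s):
        x = np.asarray(s, dtype=float)[..., 0]
        return np.stack([4.0 * barrier * x / a**2 * ((x / a) ** 2 - 1.0)],
                        axis=-1)

    return ToyPotential(value=v, gradient=g,
                        bounds=((-2.5 * a, 2.5 * a),), ndim=1)


def harmonic(k: float = 1.0) -> ToyPotential:
    """1D harmonic well V = k/2 s^2."""
    def v(s):
        x = np.asarray(s, dtype=float)[..., 0]
        return 0.5 * k * x * x

    def g(s):
        x = np.asarray(s, dtype=float)[..., 0]
        return np.stack([k * x], axis=-1)

    return ToyPotential(value=v, gradient=g, bounds=((-10.0, 10.0),), ndim=1)


@dataclass
class BiasState:
    """Gaussian hill history of a well-tempered metadynamics run."""
    h0: float = 0.3               # initial hill height, kcal/mol
    sigma: float = 0.2            # hill width, CV units
    gamma: float = 10.0           # bias factor (T + dT)/T, > 1
    temperature: float = 300.0    # K
    stride: int = 200             # deposition stride, steps
    centers: list = field(default_factory=list)
    heights: list = field(default_factory=list)

    def __post_init__(self):
        if self.gamma <= 1.0:
            raise ValueError("bias factor gamma must exceed 1")
        if self.h0 <= 0 or self.sigma <= 0:
            raise ValueError("hill height and width must be positive")

    @property
    def delta_t(self) -> float:
        return (self.gamma - 1.0) * self.temperature

    def _centers_array(self):
        return np.asarray(self.centers, dtype=float)

    def bias_value(self, s) -> np.ndarray:
        """V_bias at point(s) ``s`` (shape (..., ndim))."""
        s = np.atleast_2d(np.asarray(s, dtype=float))
        if not self.centers:
            return np.zeros(s.shape[0])
        c = self._centers_array()
        h = np.asarray(self.heights)
        d2 = ((s[:, None, :] - c[None, :, :]) ** 2).sum(axis=-1)
        return (h[None, :] * np.exp(-d2 / (2.0 * self.sigma ** 2))).sum(axis=1)

    def bias_force(self, s) -> np.ndarray:
        """-grad V_bias at a single point ``s``."""
        s = np.asarray(s, dtype=float)
        if not self.centers:
            return np.zeros_like(s)
        c = self._centers_array()
        h = np.asarray(self.heights)
        diff = s[None, :] - c
        d2 = (diff ** 2).sum(axis=-1)
        gauss = h * np.exp(-d2 / (2.0 * self.sigma ** 2))
        return (gauss[:, None] * diff / self.sigma ** 2).sum(axis=0)


def deposit_hill(bias: BiasState, s_now) -> BiasState:
    """Append a hill at ``s_now`` with the well-tempered height rule.

    Mutates and returns ``bias``. The first hill has height exactly h0; at
    a revisited point the height decays as exp(-V_bias/(kB*dT)), so in the
    gamma -> infinity limit heights stay constant (standard metadynamics).
    """
    s_now = np.atleast_1d(np.asarray(s_now, dtype=float))
    vb = float(bias.bias_value(s_now)[0])
    height = bias.h0 * np.exp(-vb / (KB * bias.delta_t))
    bias.centers.append(list(s_now))
    bias.heights.append(float(height))
    return bias


def langevin_run(potential: ToyPotential, bias: BiasState | None,
                 T: float, friction: float, dt: float, n_steps: int,
                 seed: int, s0=None):
    """Overdamped Langevin trajectory on ``potential`` (+ current bias).

    Update: ``s += (F/friction) dt + sqrt(2 kB T dt / friction) xi`` with
    reflecting walls at the potential's bounds. If ``bias`` is given, a
    hill is deposited every ``bias.stride`` steps (mutating ``bias``).
    Fully reproducible from ``seed``.
    """
    rng = np.random.default_rng(seed)
    ndim = potential.ndim
    lo = np.array([b[0] for b in potential.bounds], dtype=float)
    hi = np.array([b[1] for b in potential.bounds], dtype=float)
    if s0 is None:
        s = (lo + hi) / 2.0
    else:
        s = np.atleast_1d(np.asarray(s0, dtype=float)).copy()
    noise_scale = np.sqrt(2.0 * KB * T * dt / friction)
    traj = np.empty((n_steps, ndim))
    for step in range(n_steps):
        force = -potential.gradient(s[None, :])[0]
        if bias is not None and bias.centers:
            force = force + bias.bias_force(s)
        s = s + force * dt / friction + noise_scale * rng.normal(size=ndim)
        # reflecting boundaries
        s = np.where(s < lo, 2 * lo - s, s)
        s = np.where(s > hi, 2 * hi - s, s)
        s = np.clip(s, lo, hi)
        traj[step] = s
        if bias is not None and (step + 1) % bias.stride == 0:
            deposit_hill(bias, s)
    return traj


def reconstruct_fes(bias: BiasState, grid) -> np.ndarray:
    """Free-energy profile on ``grid`` from the accumulated bias.

    ``grid``: array of CV points, shape (n,) for 1D or (n, ndim). Returns
    F(s) = -(gamma/(gamma-1)) V_bias(s), shifted so its minimum is zero
    (flat zero for an empty bias).
    """
    grid = np.asarray(grid, dtype=float)
    if grid.ndim == 1:
        grid = grid[:, None]
    if not bias.centers:
        return np.zeros(grid.shape[0])
    vb = bias.bias_value(grid)
    fes = -(bias.gamma / (bias.gamma - 1.0)) * vb
    return fes - fes.min()
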