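"""Synthetic data generation: Brownian trajectories and PFGSTE decays.

This module replaces the instrument and the MD engine.  It produces seeded
Brownian-dynamics trajectories with a prescribed (possibly anisotropic)
translational diffusion tensor and optional isotropic rotational tumbling,
multi-component Stejskal-Tanner decays with controlled additive noise, and a
fixture of the reference concentration series (diffusion coefficient,
hydrodynamic radius, ellipsoid semi-axes).

The generator is a diffusion stand-in only: no force field, no solvation,
no inter-particle interactions.

Randomness
----------
A single integer seed governs everything.  The seed is expanded with
``numpy.random.SeedSequence`` and split per particle, and within each
particle into a displacement stream and a rotation stream, so increasing
``n_particles`` extends the ensemble without reshuffling the particles
already present.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .dosy import DecayCurve, GradientSchedule, b_factor
from .trajectory import Trajectory

__all__ = ["SimulationConfig", "NoiseSpec", "simulate_brownian_trajectory",
           "simulate_pfgste_decay", "make_table1_fixture"]


def _cov_sqrt(cov: np.ndarray) -> np.ndarray:
    """Symmetric square root of a PSD covariance; exact zeros stay zero."""
    w, v = np.linalg.eigh((cov + cov.T) / 2.0)
    return v @ np.diag(np.sqrt(np.clip(w, 0.0, None))) @ v.T


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of a Brownian-dynamics run.

    Parameters
    ----------
    n_particles, n_steps : int
        Ensemble size and number of frames (n_steps >= 2).
    dt : float
        Time step in seconds.
    body_tensor : (float, float, float)
        Principal translational diffusion coefficients (D1, D2, D3) in
        m^2 s^-1, defined in the particle body frame.
    rotational_diffusion : float
        Isotropic rotational diffusion coefficient D_r in rad^2 s^-1;
        0 disables tumbling.
    seed : int
    initial_orientation : "identity" or 3x3 rotation matrix
        Body-to-lab rotation at t = 0, shared by all particles.
    step_warn_length : float
        RMS per-step displacement (m) above which a sanity warning is
        emitted; default 1 um.
    """

    n_particles: int
    n_steps: int
    dt: float
    body_tensor: tuple
    rotational_diffusion: float = 0.0
    seed: int = 0
    initial_orientation: object = "identity"
    step_warn_length: float = 1e-6

    def __post_init__(self):
        if self.n_particles < 1:
            raise ValueError("n_particles must be >= 1")
        if self.n_steps < 2:
            raise ValueError("n_steps must be >= 2")
        if not self.dt > 0:
            raise ValueError("dt must be positive")
        d = np.asarray(self.body_tensor, dtype=float)
        if d.shape != (3,) or not np.all(np.isfinite(d)) or np.any(d < 0):
            raise ValueError("body_tensor must be three finite non-negative "
                             "diffusion coefficients")
        if not (np.isfinite(self.rotational_diffusion)
                and self.rotational_diffusion >= 0):
            raise ValueError("rotational_diffusion must be finite and >= 0")
        object.__setattr__(self, "body_tensor", tuple(d))

    @property
    def initial_rotation_matrix(self) -> np.ndarray:
        if isinstance(self.initial_orientation, str):
            if self.initial_orientation != "identity":
                raise ValueError("initial_orientation must be 'identity' or "
                                 "a 3x3 rotation matrix")
            return np.eye(3)
        R = np.asarray(self.initial_orientation, dtype=float)
        if R.shape != (3, 3) or not np.allclose(R @ R.T, np.eye(3),
                                                atol=1e-10):
            raise ValueError("initial_orientation matrix must be orthogonal")
        return R


@dataclass(frozen=True)
class NoiseSpec:
    """Additive Gaussian noise level for simulated decays.

    ``snr`` is the ratio of the unattenuated (zero-gradient) signal to the
    noise standard deviation; ``math.inf`` means noiseless.  The noise is
    additive Gaussian on the signal magnitude, appropriate to the high-SNR
    regime of the experiments being emulated (not Rician).
    """

    snr: float = math.inf
    seed: int = 0

    def __post_init__(self):
        if not self.snr > 0:
            raise ValueError("snr must be positive")


def simulate_brownian_trajectory(config: SimulationConfig) -> Trajectory:
    """Euler-Maruyama Brownian motion with an anisotropic body tensor.

    Each displacement step is drawn with covariance ``2 D_lab dt`` where
    ``D_lab = R diag(D1, D2, D3) R^T`` and ``R`` is the particle's current
    body-to-lab rotation.  Tumbling composes, between translation steps, a
    small random rotation whose rotation-vector components have variance
    ``2 D_r dt`` per axis — standard isotropic rotational diffusion.
    """
    d_body = np.asarray(config.body_tensor)
    rms_step = math.sqrt(2.0 * d_body.max() * config.dt)
    if rms_step > config.step_warn_length:
        warnings.warn(
            f"rms step {rms_step:.2e} m exceeds the sanity bound "
            f"{config.step_warn_length:.2e} m; check dt and the tensor",
            stacklevel=2)

    times = np.arange(config.n_steps) * config.dt
    positions = np.zeros((config.n_particles, config.n_steps, 3))
    r0 = config.initial_rotation_matrix
    children = np.random.SeedSequence(config.seed).spawn(config.n_particles)
    dr = config.rotational_diffusion
    rot_sigma = math.sqrt(2.0 * dr * config.dt)

    for p, child in enumerate(children):
        disp_ss, rot_ss = child.spawn(2)
        rng = np.random.default_rng(disp_ss)
        if dr == 0.0:
            d_lab = r0 @ np.diag(d_body) @ r0.T
            L = _cov_sqrt(2.0 * d_lab * config.dt)
            steps = rng.standard_normal((config.n_steps - 1, 3)) @ L.T
        else:
            rng_rot = np.random.default_rng(rot_ss)
            rotvecs = rng_rot.standard_normal((config.n_steps - 1, 3)) \
                * rot_sigma
            increments = Rotation.from_rotvec(rotvecs).as_matrix()
            cum = np.empty((config.n_steps - 1, 3, 3))
            R = r0
            for k in range(config.n_steps - 1):
                cum[k] = R
                R = increments[k] @ R
            # body tensor is diagonal: draw steps in the body frame and
            # rotate into the lab frame, equivalent to sampling N(0, 2 D_lab dt)
            body_steps = rng.standard_normal((config.n_steps - 1, 3)) \
                * np.sqrt(2.0 * d_body * config.dt)
            steps = np.einsum("kij,kj->ki", cum, body_steps)
        positions[p, 1:] = np.cumsum(steps, axis=0)
    return Trajectory(times, positions)


def simulate_pfgste_decay(components, schedule: GradientSchedule,
                          noise: NoiseSpec = NoiseSpec()) -> DecayCurve:
    """Multi-component Stejskal-Tanner decay with additive Gaussian noise.

    Parameters
    ----------
    components : sequence of (weight, D)
        Positive amplitudes and diffusion coefficients (m^2 s^-1).
    schedule : GradientSchedule
    noise : NoiseSpec
        Noise standard deviation is ``sum(weights) / snr``.
    """
    comps = [(float(w), float(d)) for w, d in components]
    if not comps:
        raise ValueError("at least one (weight, D) component required")
    for w, d in comps:
        if not w > 0:
            raise ValueError("component weights must be positive")
        if not d > 0:
            raise ValueError("component diffusion coefficients must be "
                             "positive")
    b = b_factor(schedule)
    signal = np.zeros_like(b)
    for w, d in comps:
        signal += w * np.exp(-b * d)
    if math.isfinite(noise.snr):
        total = sum(w for w, _ in comps)
        rng = np.random.default_rng(noise.seed)
        signal = signal + rng.normal(0.0, total / noise.snr, size=b.size)
    return DecayCurve(gradients=schedule.gradients, intensities=signal,
                      schedule=schedule)


#: (concentration mM, D m^2/s, R_h nm, a nm, b nm) — the printed reference
#: concentration series used as a regression fixture.
_TABLE1 = (
    (0.52, 3.40e-10, 0.64, 2.1, 0.16),
    (1.05, 3.50e-10, 0.61, 2.1, 0.14),
    (2.60, 3.46e-10, 0.63, 2.1, 0.15),
    (3.50, 3.46e-10, 0.63, 2.1, 0.15),
    (5.25, 3.46e-10, 0.63, 2.1, 0.15),
)


def make_table1_fixture() -> pd.DataFrame:
    """The published concentration series, verbatim, as a DataFrame.

    Columns: ``concentration_mM``, ``D_m2_s``, ``expected_rh_nm``,
    ``expected_a_nm``, ``expected_b_nm``.
    """
    return pd.DataFrame(
        _TABLE1, columns=["concentration_mM", "D_m2_s", "expected_rh_nm",
                          "expected_a_nm", "expected_b_nm"])


def write_decay_csv(decay: DecayCurve, path) -> None:
    """Write ``gradient_G_per_cm,intensity`` rows."""
    pd.DataFrame({
        "gradient_G_per_cm": decay.gradients / 1e-2,
        "intensity": decay.intensities,
    }).to_csv(path, index=False)
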