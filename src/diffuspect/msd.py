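"""Mean-square-displacement tensor analysis of particle trajectories.

The translational diffusion of an anisotropic particle is characterized by a
symmetric tensor ``D_ab``.  Each of the six unique displacement products
grows linearly with lag time,

    M_ab(tau) = <delta_a(tau) delta_b(tau)> = 2 D_ab tau,

(the per-component Einstein relation), while the total three-dimensional MSD
obeys the Einstein-Smoluchowski law ``MSD = 6 D tau``.  This module computes
the six components with all-origin averaging using an FFT correlation
estimator, fits each slope over a lag window, diagonalizes the resulting
tensor, and reports the eigenvalue mean alongside the isotropic 6Dt fit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .trajectory import Trajectory

__all__ = ["COMPONENT_NAMES", "MSDTensorSeries", "DiffusionTensorResult",
           "compute_msd_components", "fit_diffusion_tensor",
           "diagonalize_tensor", "MSDDiffusionModel"]

#: Order of the six unique tensor components throughout this module.
COMPONENT_NAMES = ("xx", "yy", "zz", "xy", "xz", "yz")

_PAIRS = ((0, 0), (1, 1), (2, 2), (0, 1), (0, 2), (1, 2))


@dataclass(frozen=True)
class MSDTensorSeries:
    """Lag-time series of the six unique MSD components.

    Parameters
    ----------
    lags : ndarray, shape (n_lags,)
        Lag times in seconds, starting at 0.
    components : ndarray, shape (n_lags, 6)
        ``M_xx, M_yy, M_zz, M_xy, M_xz, M_yz`` in m^2, in the order of
        :data:`COMPONENT_NAMES`.
    n_samples : ndarray, shape (n_lags,)
        Number of (origin, particle) pairs averaged at each lag.
    """

    lags: np.ndarray
    components: np.ndarray
    n_samples: np.ndarray

    def __post_init__(self):
        lags = np.asarray(self.lags, dtype=float)
        comp = np.asarray(self.components, dtype=float)
        ns = np.asarray(self.n_samples)
        if comp.shape != (lags.size, 6):
            raise ValueError("components must have shape (n_lags, 6)")
        object.__setattr__(self, "lags", lags)
        object.__setattr__(self, "components", comp)
        object.__setattr__(self, "n_samples", ns)

    @property
    def total(self) -> np.ndarray:
        """Total 3-D MSD, ``M_xx + M_yy + M_zz``."""
        return self.components[:, :3].sum(axis=1)

    def component(self, name: str) -> np.ndarray:
        return self.components[:, COMPONENT_NAMES.index(name)]


def compute_msd_components(traj: Trajectory,
                           max_lag: int | None = None) -> MSDTensorSeries:
    """All-origin averaged MSD tensor components.

    ``M_ab(tau)`` is the product of displacement components ``a`` and ``b``
    over lag ``tau``, averaged over every overlapping time origin and every
    particle.  The diagonal entries are the conventional per-axis MSDs.
    Uses the FFT cross-correlation identity, O(N log N) per component pair.

    Parameters
    ----------
    traj : Trajectory
        Uniformly sampled; non-uniform spacing is rejected.
    max_lag : int, optional
        Largest lag index (frames); defaults to ``n_frames - 1`` and must be
        smaller than the number of frames.
    """
    dt = traj.dt  # validates uniform spacing, >= 2 frames
    n = traj.n_frames
    if max_lag is None:
        max_lag = n - 1
    if not 0 < max_lag < n:
        raise ValueError("max_lag must satisfy 0 < max_lag < n_frames")

    # centering leaves displacements unchanged but makes constant
    # trajectories exactly zero and improves FFT conditioning
    pos = traj.positions - traj.positions.mean(axis=1, keepdims=True)
    nfft = 2 * n
    F = np.fft.rfft(pos, n=nfft, axis=1)  # (P, nfft//2+1, 3)
    lags_idx = np.arange(max_lag + 1)
    counts = (n - lags_idx) * traj.n_particles

    comp = np.empty((max_lag + 1, 6))
    for c, (a, b) in enumerate(_PAIRS):
        # sum over origins of a(t)b(t+tau) + b(t)a(t+tau), all particles
        cross = np.fft.irfft(np.conj(F[:, :, a]) * F[:, :, b]
                             + np.conj(F[:, :, b]) * F[:, :, a],
                             n=nfft, axis=1)[:, :max_lag + 1]
        q = pos[:, :, a] * pos[:, :, b]  # (P, N)
        csum = np.concatenate([np.zeros((traj.n_particles, 1)),
                               np.cumsum(q, axis=1)], axis=1)
        total_q = csum[:, -1:]
        # S1(tau) = sum_{t<=N-1-tau} q(t) + sum_{t>=tau} q(t)
        s1 = csum[:, n - lags_idx] + (total_q - csum[:, lags_idx])
        comp[:, c] = (s1 - cross).sum(axis=0) / counts
    comp[0, :] = 0.0  # lag 0 is identically zero up to round-off
    return MSDTensorSeries(lags=lags_idx * dt, components=comp,
                           n_samples=counts)


@dataclass(frozen=True)
class DiffusionTensorResult:
    """Fitted diffusion tensor with its spectral decomposition.

    Attributes
    ----------
    tensor : ndarray (3, 3)
        Symmetric diffusion tensor, m^2 s^-1.
    eigenvalues : ndarray (3,)
        Principal diffusion coefficients, sorted descending.
    eigenvectors : ndarray (3, 3)
        Orthonormal columns matching ``eigenvalues``.
    mean_D : float
        Eigenvalue average, equal to trace/3.
    isotropic_D : float
        One sixth of the total-MSD slope over the same window.
    fit_window : (float, float)
        Lag interval used, seconds.
    fit_r2 : ndarray (6,)
        Coefficient of determination per component, order of
        :data:`COMPONENT_NAMES`.
    """

    tensor: np.ndarray
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    mean_D: float
    isotropic_D: float
    fit_window: tuple
    fit_r2: np.ndarray

    @property
    def anisotropy(self) -> float:
        """Ratio of largest to smallest principal diffusion coefficient."""
        lo = self.eigenvalues[2]
        return float(self.eigenvalues[0] / lo) if lo > 0 else np.inf

    def summary(self) -> str:
        t = self.tensor
        lines = [
            "Diffusion tensor fit (per-component Einstein relation)",
            "------------------------------------------------------",
            f"fit window    {self.fit_window[0]:.4g} .. "
            f"{self.fit_window[1]:.4g} s",
            "tensor [m^2/s]",
        ]
        for row in t:
            lines.append("    " + "  ".join(f"{v: .4e}" for v in row))
        lines += [
            "eigenvalues   " + "  ".join(f"{v:.4e}"
                                         for v in self.eigenvalues),
            f"mean_D        {self.mean_D:.6e} m^2/s  (eigenvalue average)",
            f"isotropic_D   {self.isotropic_D:.6e} m^2/s  (6Dt fit)",
            "r^2           " + "  ".join(
                f"{n}={r:.4f}" for n, r in zip(COMPONENT_NAMES,
                                               self.fit_r2)),
        ]
        return "\n".join(lines)


def _slope_r2(x: np.ndarray, y: np.ndarray):
    slope, intercept = np.polyfit(x, y, 1)
    fit = slope * x + intercept
    ss_res = float(np.sum((y - fit) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return float(slope), r2


def fit_diffusion_tensor(series: MSDTensorSeries,
                         window: tuple | None = None
                         ) -> DiffusionTensorResult:
    """Fit ``D_ab`` from the slopes of the six MSD components.

    Each ``D_ab`` is half the least-squares slope (free intercept) of
    ``M_ab`` against lag over the window; ``isotropic_D`` is one sixth of
    the total-MSD slope over the same window.

    Parameters
    ----------
    series : MSDTensorSeries
    window : (lag_min, lag_max), seconds, optional
        Defaults to 10%..50% of the largest available lag, the near-linear
        regime away from both the noisy origin and the poorly averaged tail.
    """
    lags = series.lags
    if window is None:
        window = (0.1 * lags[-1], 0.5 * lags[-1])
    lo, hi = float(window[0]), float(window[1])
    mask = (lags >= lo) & (lags <= hi)
    if mask.sum() < 3:
        raise ValueError(
            f"fit window [{lo:g}, {hi:g}] s contains "
            f"{int(mask.sum())} lag points; >= 3 required")
    x = lags[mask]
    slopes = np.empty(6)
    r2 = np.empty(6)
    for c in range(6):
        slopes[c], r2[c] = _slope_r2(x, series.components[mask, c])
    d = slopes / 2.0
    tensor = np.array([[d[0], d[3], d[4]],
                       [d[3], d[1], d[5]],
                       [d[4], d[5], d[2]]])
    total_slope, _ = _slope_r2(x, series.total[mask])
    eigenvalues, eigenvectors = diagonalize_tensor(tensor)
    return DiffusionTensorResult(
        tensor=tensor, eigenvalues=eigenvalues, eigenvectors=eigenvectors,
        mean_D=float(np.trace(tensor) / 3.0),
        isotropic_D=float(total_slope / 6.0),
        fit_window=(lo, hi), fit_r2=r2)


def diagonalize_tensor(tensor) -> tuple:
    """Eigenvalues (descending) and orthonormal eigenvectors of a symmetric
    diffusion tensor.

    Accepts a 3x3 array or a :class:`DiffusionTensorResult`.  Asymmetry
    beyond 1e-12 (relative to the tensor norm) is an error.
    """
    if isinstance(tensor, DiffusionTensorResult):
        tensor = tensor.tensor
    t = np.asarray(tensor, dtype=float)
    if t.shape != (3, 3):
        raise ValueError("tensor must be 3x3")
    scale = max(np.abs(t).max(), 1e-300)
    if np.abs(t - t.T).max() > 1e-12 * scale:
        raise ValueError("tensor is not symmetric within tolerance")
    w, v = np.linalg.eigh((t + t.T) / 2.0)
    order = np.argsort(w)[::-1]
    return w[order], v[:, order]


class MSDDiffusionModel:
    """Diffusion-tensor model of a trajectory.

    Wraps MSD computation and tensor fitting in the model/results idiom::

        result = MSDDiffusionModel(traj).fit()
        print(result.summary())

    Parameters
    ----------
    traj : Trajectory
    max_lag : int, optional
        Largest lag (frames) carried into the MSD series.
    """

    def __init__(self, traj: Trajectory, max_lag: int | None = None):
        self.traj = traj
        self.max_lag = max_lag
        self._series = None

    @property
    def series(self) -> MSDTensorSeries:
        if self._series is None:
            self._series = compute_msd_components(self.traj, self.max_lag)
        return self._series

    def fit(self, window: tuple | None = None) -> DiffusionTensorResult:
        return fit_diffusion_tensor(self.series, window=window)

    def plot(self, ax=None):
        """Plot the six MSD components against lag (requires matplotlib)."""
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        for c, name in enumerate(COMPONENT_NAMES):
            ax.plot(self.series.lags, self.series.components[:, c],
                    label=f"M_{name}")
        ax.set_xlabel("lag [s]")
        ax.set_ylabel(r"MSD [m$^2$]")
        ax.legend()
        return ax
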