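"""Lateral diffusion from trajectories: 2D MSD and the Einstein relation.

The protein's in-plane motion is measured relative to the membrane
centre of mass (drift removal), the two-dimensional mean-square displacement
MSD(τ) is averaged over all time origins, and D is the slope of the linear
regime divided by 4 (MSD = 4Dτ in two dimensions).  Internally Å²/ns;
1 Å²/ns = 1e-7 cm²/s at the reporting boundary.

The all-origin MSD uses the FFT autocorrelation identity, so 10⁴-step
series cost O(n log n); a double-loop oracle in the test suite pins the
two routes together.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .model import SystemModel, Trajectory

__all__ = [
    "MSDSeries",
    "DiffusionEstimate",
    "remove_reference_motion",
    "compute_msd_2d",
    "fit_einstein_2d",
    "A2_PER_NS_TO_CM2_PER_S",
]

A2_PER_NS_TO_CM2_PER_S = 1e-7


@dataclass
class MSDSeries:
    lag: np.ndarray  # ns, strictly increasing, lag[0] = 0
    msd: np.ndarray  # Å²
    n_origins: np.ndarray  # time-origin pairs contributing to each lag

    def __post_init__(self) -> None:
        self.lag = np.asarray(self.lag, dtype=float)
        self.msd = np.asarray(self.msd, dtype=float)
        self.n_origins = np.asarray(self.n_origins, dtype=int)
        if np.any(self.msd < -1e-9):
            raise ValueError("MSD must be nonnegative")
        if np.any(np.diff(self.lag) <= 0):
            raise ValueError("lags must be strictly increasing")


@dataclass
class DiffusionEstimate:
    D: float  # cm²/s
    D_err: float  # cm²/s, two-block half-spread
    slope: float  # Å²/ns
    fit_window: tuple[float, float]  # ns
    r_squared: float
    method: str = "ols slope/4; uncertainty = half-spread of two-block split"


def remove_reference_motion(traj: Trajectory, system: SystemModel,
                            mobile_group: str,
                            reference_group: str) -> np.ndarray:
    """xy positions (Å) of the mobile-group COM relative to the reference COM.

    Both centres of mass are mass-weighted.  Returns an (n_frames, 2) array;
    rigid drift applied equally to both groups cancels exactly.
    """
    mob = system.group_indices(mobile_group)
    ref = system.group_indices(reference_group)
    if mob.size == 0 or ref.size == 0:
        raise ValueError("mobile and reference groups must be non-empty")
    masses = system.masses
    m_mob = masses[mob]
    m_ref = masses[ref]
    out = np.empty((len(traj), 2))
    for i, frame in enumerate(traj):
        com_mob = (m_mob[:, None] * frame.coordinates[mob]).sum(0) / m_mob.sum()
        com_ref = (m_ref[:, None] * frame.coordinates[ref]).sum(0) / m_ref.sum()
        out[i] = (com_mob - com_ref)[:2]
    return out


def _msd_fft_1d(x: np.ndarray) -> np.ndarray:
    """All-origin MSD of a 1D series for lags 0..n-1 (FFT autocorrelation)."""
    n = len(x)
    nfft = 1 << (2 * n - 1).bit_length()
    fx = np.fft.rfft(x, nfft)
    acf = np.fft.irfft(fx * np.conj(fx), nfft)[:n]
    sq = x * x
    # S1(m) = sum_{k} [x_k^2 + x_{k+m}^2] over valid origins, via suffix sums
    cum = np.concatenate(([0.0], np.cumsum(sq)))
    total = cum[-1]
    s1 = np.empty(n)
    for m in range(n):
        s1[m] = (total - cum[m]) + (total - (cum[-1] - cum[n - m]))
    counts = n - np.arange(n)
    return (s1 - 2.0 * acf) / counts


def compute_msd_2d(positions: np.ndarray, dt: float,
                   max_lag_fraction: float = 0.5) -> MSDSeries:
    """All-origin 2D MSD of one or more walkers.

    ``positions``: (n_frames, 2) or (n_walkers, n_frames, 2) in Å; walkers
    are averaged with equal weight per origin.  Lags run from 0 up to
    ``max_lag_fraction`` of the series length.
    """
    pos = np.asarray(positions, dtype=float)
    if pos.ndim == 2:
        pos = pos[None]
    n_walkers, n_frames, _ = pos.shape
    if n_frames < 2:
        raise ValueError("need at least two frames")
    msd = np.zeros(n_frames)
    for wi in range(n_walkers):
        msd += _msd_fft_1d(pos[wi, :, 0]) + _msd_fft_1d(pos[wi, :, 1])
    msd /= n_walkers
    max_lag = max(int(np.floor(max_lag_fraction * (n_frames - 1))), 1)
    lags = np.arange(max_lag + 1)
    return MSDSeries(lag=lags * dt, msd=np.maximum(msd[: max_lag + 1], 0.0),
                     n_origins=(n_frames - lags) * n_walkers)


def fit_einstein_2d(msd: MSDSeries,
                    window: tuple[float, float] | None = None,
                    positions: np.ndarray | None = None,
                    dt: float | None = None) -> DiffusionEstimate:
    """Least-squares fit of MSD(τ) over a lag window; D = slope/4 in cm²/s.

    ``window`` defaults to the first half of the available lags (the regime
    where simulated membrane-protein MSD is approximately linear).  If the
    raw ``positions`` are supplied, D_err is the half-spread of D refit on
    the two halves of the series (block estimate), otherwise 0.
    """
    if window is None:
        window = (0.0, float(msd.lag[-1]) / 2.0)
    lo, hi = window
    mask = (msd.lag >= lo) & (msd.lag <= hi)
    if mask.sum() < 3:
        raise ValueError("fit window must contain at least 3 lags")
    fit = stats.linregress(msd.lag[mask], msd.msd[mask])
    slope = float(fit.slope)
    D = slope / 4.0 * A2_PER_NS_TO_CM2_PER_S

    D_err = 0.0
    if positions is not None:
        if dt is None:
            raise ValueError("dt required with positions for the block estimate")
        pos = np.asarray(positions, dtype=float)
        if pos.ndim == 2:
            pos = pos[None]
        half = pos.shape[1] // 2
        Ds = []
        for block in (pos[:, :half], pos[:, half:]):
            m = compute_msd_2d(block, dt)
            bmask = (m.lag >= lo) & (m.lag <= min(hi, m.lag[-1]))
            if bmask.sum() < 3:
                bmask = np.ones_like(m.lag, dtype=bool)
            bfit = stats.linregress(m.lag[bmask], m.msd[bmask])
            Ds.append(bfit.slope / 4.0 * A2_PER_NS_TO_CM2_PER_S)
        D_err = abs(Ds[0] - Ds[1]) / 2.0

    return DiffusionEstimate(D=D, D_err=D_err, slope=slope,
                             fit_window=(float(lo), float(hi)),
                             r_squared=float(fit.rvalue ** 2))
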