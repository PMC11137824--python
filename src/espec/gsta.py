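"""Trajectory quantization by generalized smoothed trajectory analysis.

A classical trajectory samples nuclear motion with classical thermal
amplitudes.  For a harmonic mode of frequency ``nu`` at temperature ``T``
the ratio of the quantum to the classical oscillator energy is

    w(nu) = (h nu / 2 k_B T) * coth(h nu / 2 k_B T)

which tends to 1 for ``h nu << k_B T`` (classical limit) and to the
zero-point-dominated ``h nu / 2 k_B T`` for stiff modes.  Convolving each
Cartesian coordinate with a kernel whose frequency-domain gain is
``sqrt(w(nu))`` therefore leaves slow motions untouched while amplifying
the amplitude of fast vibrations exactly so that every quadratic observable
(mode energy, position variance) acquires its quantum thermal value.  The
kernel is built by sampling ``sqrt(w)`` on the FFT frequencies of a moving
window (100-200 fs), inverse transforming and centering; the filtered
("quantized") trajectory drops half a window at each end rather than
padding, since padding would fabricate dynamics.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import fftconvolve

from .core_io import H_EV_FS, KB_EV_K, Trajectory


def weight(nu, T: float):
    """Quantum/classical harmonic-oscillator energy ratio w(nu).

    ``nu`` in fs^-1 (cycles per fs), ``T`` in K; w(0) = 1 by the classical
    limit, and w -> h nu / (2 k_B T) for h nu >> k_B T.
    """
    if T <= 0:
        raise ValueError("temperature must be positive")
    nu = np.asarray(nu, dtype=float)
    if np.any(nu < 0):
        raise ValueError("frequency must be nonnegative")
    x = H_EV_FS * nu / (2.0 * KB_EV_K * T)
    # x*coth(x) with the x->0 limit of 1; tanh is overflow-safe
    out = np.where(x < 1e-8, 1.0, x / np.tanh(np.where(x < 1e-8, 1.0, x)))
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class FilterKernel:
    """Discrete symmetric filter kernel g for one window.

    ``g`` has odd length ``W/dt`` (rounded up to odd), sums to 1 (unit DC
    gain) and its discrete transfer gain at each FFT frequency of the window
    equals sqrt(w(nu)) by construction.
    """

    g: np.ndarray
    dt_fs: float
    window_fs: float
    temperature: float

    @property
    def half_width(self) -> int:
        return (len(self.g) - 1) // 2

    def transfer_gain(self, nu) -> np.ndarray:
        """DTFT magnitude of the kernel at arbitrary frequency nu (fs^-1)."""
        nu = np.atleast_1d(np.asarray(nu, dtype=float))
        j = np.arange(len(self.g)) - self.half_width
        ph = np.exp(-2j * np.pi * nu[:, None] * j[None, :] * self.dt_fs)
        return np.abs(ph @ self.g)


def build_kernel(dt_fs: float, window_fs: float = 150.0,
                 T: float = 300.0) -> FilterKernel:
    """Construct the filter kernel for sampling interval ``dt_fs``.

    Samples sqrt(w) at the window's FFT frequencies, inverse transforms,
    centers and renormalizes to unit sum.  The window must hold at least 8
    samples to represent sqrt(w).
    """
    n = int(round(window_fs / dt_fs))
    if n < 8:
        raise ValueError("window too short to represent the weight function")
    if n % 2 == 0:
        n += 1  # odd length => exactly symmetric discrete kernel
    freqs = np.abs(np.fft.fftfreq(n, d=dt_fs))
    gain = np.sqrt(weight(freqs, T))
    g = np.fft.fftshift(np.fft.ifft(gain).real)
    g /= g.sum()
    return FilterKernel(g=g, dt_fs=dt_fs, window_fs=window_fs, temperature=T)


def filter_trajectory(traj: Trajectory, kernel: FilterKernel) -> Trajectory:
    """Convolve every Cartesian coordinate with the kernel (moving window).

    Operates on the dense trajectory (spacing must match the kernel; the OH
    stretch must lie below Nyquist, so dt <= 4 fs).  Velocities, when
    present, are filtered identically.  Edge margins of half a window are
    dropped at both ends; the result is tagged ``quantized``.
    """
    if abs(traj.dt_fs - kernel.dt_fs) > 1e-9:
        raise ValueError("trajectory spacing does not match kernel")
    if traj.dt_fs > 4.0:
        raise ValueError("trajectory too coarse: OH stretch above Nyquist")
    if traj.n_frames < len(kernel.g):
        raise ValueError("trajectory shorter than the filter window")
    k3 = kernel.g[:, None, None]
    pos = fftconvolve(traj.positions, k3, mode="valid", axes=0)
    vel = None
    if traj.velocities is not None:
        vel = fftconvolve(traj.velocities, k3, mode="valid", axes=0)
    return replace(traj, positions=pos, velocities=vel,
                   t0=traj.t0 + kernel.half_width * traj.dt_fs,
                   tag="quantized")


def filter_series(x: np.ndarray, kernel: FilterKernel) -> np.ndarray:
    """Filter a plain 1D series (oracle/diagnostic helper)."""
    return np.convolve(np.asarray(x, dtype=float), kernel.g, mode="valid")
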