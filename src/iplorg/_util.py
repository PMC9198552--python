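"""Shared numerical helpers (axial Fourier shifts, seeded RNG trees)."""

from __future__ import annotations

import numpy as np
from scipy import fft as sp_fft


def axial_fourier_shift(volume: np.ndarray, shift) -> np.ndarray:
    """Shift a (z, y, x) volume along z by a fractional number of voxels.

    Uses the Fourier shift theorem, so fractional shifts are exact in the
    band-limited sense and the complex phase carried by each A-scan moves
    rigidly with the structure.  ``shift`` may be a scalar (global axial
    motion) or a (y, x) map (per-A-scan flattening); positive values move
    content toward larger z (deeper).  Single-precision complex input stays
    single precision.
    """
    volume = np.asarray(volume)
    nz = volume.shape[0]
    k = np.fft.fftfreq(nz)[:, None, None]
    shift = np.asarray(shift, dtype=float)
    if shift.ndim == 0:
        ramp = np.exp(-2j * np.pi * k * shift)
    else:
        if shift.shape != volume.shape[1:]:
            raise ValueError(
                f"shift map shape {shift.shape} != lateral shape {volume.shape[1:]}"
            )
        ramp = np.exp(-2j * np.pi * k * shift[None, :, :])
    if volume.dtype == np.complex64:
        ramp = ramp.astype(np.complex64)
    spec = sp_fft.fft(volume, axis=0)
    out = sp_fft.ifft(spec * ramp, axis=0)
    if not np.iscomplexobj(volume):
        return out.real.astype(volume.dtype)
    return out.astype(volume.dtype)


def child_rng(seed: int, *path: int) -> np.random.Generator:
    """Deterministic per-stage generator derived from one master seed.

    Every stochastic stage of the package draws from its own child stream so
    that regenerating any single stage is reproducible independently of the
    others.
    """
    return np.random.default_rng(np.random.SeedSequence([int(seed), *path]))
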