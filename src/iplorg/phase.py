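"""Temporal cross-spectra and consistent-phase solving for IPL sub-layers.

The functional signal of interest is a nanometre-scale change of the optical
path length (OPL) between a shallow band of voxels inside the inner plexiform
layer (IPL) and a fixed reference band just below its segmented lower edge.
In phase-sensitive OCT that change appears as a temporal phase difference of
the complex backscattered field.  Because the speckle field decorrelates over
time, the phase difference between two particular volumes is noisy; the
evaluation therefore

1. forms the temporal cross-spectrum ``dU(t, dt) = U(t) * conj(U(t + dt))``
   for a small set of volume lags,
2. pairs two depth bands (two voxels each) against each other by coherently
   summing their cross-spectra and multiplying one with the conjugate of the
   other,
3. ensemble-averages the paired cross-spectrum laterally with a circular
   Gaussian (sigma = 4 px), and
4. solves, per lateral pixel, for one phase time course ``phi(t)`` that is
   consistent with *all* entries of the averaged cross-spectrum — an extended
   Knox-Thompson scheme, implemented here as magnitude-weighted nonlinear
   least squares on wrapped residuals.

Phase converts to OPL with the double-pass reflection factor
``dl = phi * lambda0 / (4 pi)``.
"""

from __future__ import annotations

import dataclasses
from typing import Dict, Mapping, Sequence, Tuple

import numpy as np

#: Lateral standard deviation (pixels) of the ensemble-averaging Gaussian.
ENSEMBLE_SIGMA = 4.0

#: Volume-step lags used by the consistent-phase solver.
DEFAULT_LAGS = (1, 2, 3, 4)


def wrap_phase(x: np.ndarray) -> np.ndarray:
    """Wrap angles into (-pi, pi]."""
    return np.angle(np.exp(1j * np.asarray(x)))


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class LayerBand:
    """A two-voxel depth band at constant offset from the flattened IPL edge.

    ``offsets`` are z offsets in voxels relative to the flattened lower IPL
    edge; negative offsets lie *above* the edge (shallower, inside the IPL),
    positive offsets below it.
    """

    name: str
    offsets: Tuple[int, int]

    def __post_init__(self):
        if len(self.offsets) != 2 or self.offsets[1] != self.offsets[0] + 1:
            raise ValueError("a band consists of exactly 2 consecutive voxels")

    def indices(self, target_plane: int) -> np.ndarray:
        return np.asarray(self.offsets) + int(target_plane)

    def overlaps(self, other: "LayerBand") -> bool:
        return bool(set(self.offsets) & set(other.offsets))


#: Default band geometry: three IPL sub-layer bands above the flattened lower
#: edge and a reference band below it, each two voxels deep with one-voxel
#: gaps (exact offsets are not dictated by the physics and are config-exposed).
DEFAULT_BANDS: Dict[str, LayerBand] = {
    "inner": LayerBand("inner", (-8, -7)),
    "central": LayerBand("central", (-5, -4)),
    "outer": LayerBand("outer", (-2, -1)),
    "reference": LayerBand("reference", (2, 3)),
}


@dataclasses.dataclass
class CrossSpectrum:
    """Temporal phase-difference phasors.

    ``values[l, t]`` holds ``U(t) * conj(U(t + lags[l]))`` (element-wise, or
    band-paired, depending on provenance); entries with ``t + lag`` beyond the
    record are zero.  Trailing axes are spatial.
    """

    values: np.ndarray
    lags: Tuple[int, ...]
    layer_pair: Tuple[str, str] | None = None

    @property
    def n_volumes(self) -> int:
        return self.values.shape[1]


@dataclasses.dataclass
class PhaseMapSeries:
    """Solved per-pixel phase time course, anchored at phi(t=0) = 0."""

    phi: np.ndarray  # (nt, ny, nx), radians
    quality: np.ndarray  # (ny, nx) mean weighted wrapped residual, radians
    lags: Tuple[int, ...] = DEFAULT_LAGS


@dataclasses.dataclass
class OPLMapSeries:
    """Optical-path-length change maps in metres."""

    opl: np.ndarray  # (nt, ny, nx), metres
    lambda0: float


# ---------------------------------------------------------------------------
# cross-spectra
# ---------------------------------------------------------------------------


def cross_spectrum(volumes: np.ndarray, lags: Sequence[int]) -> CrossSpectrum:
    """Element-wise temporal cross-spectrum ``U(t) conj(U(t+dt))``.

    Parameters
    ----------
    volumes
        Complex array with time on the first axis.
    lags
        Positive volume-step lags; every lag must be smaller than the number
        of volumes.
    """
    volumes = np.asarray(volumes)
    nt = volumes.shape[0]
    lags = tuple(int(l) for l in lags)
    if any(l < 0 or l >= nt for l in lags):
        raise ValueError(f"lags {lags} out of range for {nt} volumes")
    out = np.zeros((len(lags), nt) + volumes.shape[1:], dtype=np.complex128)
    for i, lag in enumerate(lags):
        out[i, : nt - lag] = volumes[: nt - lag] * np.conj(volumes[lag:])
    return CrossSpectrum(out, lags)


def layer_pair_cross_spectrum(
    dU: CrossSpectrum, z1: LayerBand, z2: LayerBand, target_plane: int
) -> CrossSpectrum:
    """Pair two depth bands of a full-volume cross-spectrum.

    Sums the per-voxel cross-spectra over the two voxels of each band
    (coherent averaging in depth) and multiplies the first band's sum with
    the conjugate of the second's, yielding a lateral phasor whose argument
    is the temporal change of the *differential* phase between the bands.
    """
    if z1.overlaps(z2):
        raise ValueError(f"bands {z1.name} and {z2.name} overlap")
    nz = dU.values.shape[2]
    i1, i2 = z1.indices(target_plane), z2.indices(target_plane)
    for idx in (*i1, *i2):
        if idx < 0 or idx >= nz:
            raise ValueError(f"band voxel {idx} outside volume depth {nz}")
    s1 = dU.values[:, :, i1].sum(axis=2)
    s2 = dU.values[:, :, i2].sum(axis=2)
    return CrossSpectrum(s1 * np.conj(s2), dU.lags, (z1.name, z2.name))


def band_pair_cross_spectrum(
    volumes: np.ndarray,
    z1: LayerBand,
    z2: LayerBand,
    target_plane: int,
    lags: Sequence[int] = DEFAULT_LAGS,
) -> CrossSpectrum:
    """Paired band cross-spectrum computed directly from a volume series.

    Equivalent to ``layer_pair_cross_spectrum(cross_spectrum(U, lags), ...)``
    but only ever touches the band voxels, so it is usable on full-size
    volume series without materialising the volumetric cross-spectrum.
    """
    if z1.overlaps(z2):
        raise ValueError(f"bands {z1.name} and {z2.name} overlap")
    nt, nz = volumes.shape[:2]
    lags = tuple(int(l) for l in lags)
    if any(l < 0 or l >= nt for l in lags):
        raise ValueError(f"lags {lags} out of range for {nt} volumes")
    u1 = np.ascontiguousarray(volumes[:, z1.indices(target_plane)])
    u2 = np.ascontiguousarray(volumes[:, z2.indices(target_plane)])
    out = np.zeros((len(lags), nt) + volumes.shape[2:], dtype=np.complex128)
    for i, lag in enumerate(lags):
        s1 = (u1[: nt - lag] * np.conj(u1[lag:])).sum(axis=1)
        s2 = (u2[: nt - lag] * np.conj(u2[lag:])).sum(axis=1)
        out[i, : nt - lag] = s1 * np.conj(s2)
    return CrossSpectrum(out, lags, (z1.name, z2.name))


def ensemble_average(dU: CrossSpectrum, sigma: float = ENSEMBLE_SIGMA) -> CrossSpectrum:
    """Circular lateral Gaussian ensemble average of a paired cross-spectrum.

    The complex field is convolved (wrap-around) with a unit-sum periodic
    Gaussian of standard deviation ``sigma`` pixels, independently for every
    (time, lag) entry.  Averaging complex phasors before taking arguments is
    what suppresses speckle-decorrelation phase noise.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    vals = dU.values
    ny, nx = vals.shape[-2:]
    ky = np.fft.fftfreq(ny)[:, None]
    kx = np.fft.fftfreq(nx)[None, :]
    transfer = np.exp(-2.0 * np.pi**2 * sigma**2 * (ky**2 + kx**2))
    spec = np.fft.fft2(vals, axes=(-2, -1))
    out = np.fft.ifft2(spec * transfer, axes=(-2, -1))
    return CrossSpectrum(out, dU.lags, dU.layer_pair)


# ---------------------------------------------------------------------------
# consistent-phase solver
# ---------------------------------------------------------------------------


def _cholesky_banded_factor_many(diag, off):
    """Factor many SPD banded systems at once, vectorised over a pixel axis.

    ``diag``: (n, m) diagonals; ``off``: (bw, n, m) with ``off[l-1, j]`` the
    (j+l, j) entry.  Plain banded Cholesky, written out so that tens of
    thousands of per-pixel systems factor in a single pass of n-step python
    loops over numpy-vectorised pixel axes.
    """
    n, m = diag.shape
    bw = off.shape[0]
    L_diag = np.empty_like(diag)
    L_off = np.zeros_like(off)
    for j in range(n):
        s = diag[j].copy()
        for k in range(max(0, j - bw), j):
            s -= L_off[j - k - 1, k] ** 2
        L_diag[j] = np.sqrt(np.maximum(s, 1e-300))
        for l in range(1, bw + 1):
            if j + l >= n:
                break
            s = off[l - 1, j].copy()
            for k in range(max(0, j + l - bw), j):
                s -= L_off[j + l - k - 1, k] * L_off[j - k - 1, k]
            L_off[l - 1, j] = s / L_diag[j]
    return L_diag, L_off


def _cholesky_banded_solve_many(factor, rhs):
    """Solve with a factorisation from :func:`_cholesky_banded_factor_many`."""
    L_diag, L_off = factor
    n = L_diag.shape[0]
    bw = L_off.shape[0]
    # forward substitution L y = b
    y = np.empty_like(rhs)
    for j in range(n):
        s = rhs[j].copy()
        for k in range(max(0, j - bw), j):
            s -= L_off[j - k - 1, k] * y[k]
        y[j] = s / L_diag[j]
    # back substitution L^T x = y
    x = np.empty_like(rhs)
    for j in range(n - 1, -1, -1):
        s = y[j].copy()
        for l in range(1, bw + 1):
            if j + l < n:
                s -= L_off[l - 1, j] * x[j + l]
        x[j] = s / L_diag[j]
    return x


def solve_phase(
    dU: CrossSpectrum,
    tol: float = 1e-6,
    max_iter: int = 100,
) -> PhaseMapSeries:
    """Solve for a phase time course consistent with all cross-spectrum lags.

    Per lateral pixel, finds ``phi(t)`` with ``phi(0) = 0`` minimising

        sum_{t, dt} w(t, dt) | exp(i (phi(t) - phi(t+dt))) - dU/|dU| |^2

    with magnitude weights ``w = |dU|``.  The solver initialises ``phi`` with
    the cumulative sum of the lag-1 phase differences and refines it by
    Gauss-Newton steps on the wrapped residuals until the largest update
    falls below ``tol`` radians (or ``max_iter`` iterations).

    The redundant lags reduce the random-walk variance of the lag-1
    cumulative sum; wrapping is safe for phase steps up to just below pi per
    volume as long as lag 1 is present (which is required).

    Pixels whose cross-spectrum magnitude is identically zero have no phase
    information; their time course is returned as NaN.
    """
    lags = dU.lags
    if 1 not in lags:
        raise ValueError("lag set must include dt = 1")
    vals = dU.values
    nt = vals.shape[1]
    if nt < 2:
        raise ValueError("need at least 2 volumes")
    spatial = vals.shape[2:]
    m = int(np.prod(spatial)) if spatial else 1
    vals = vals.reshape(len(lags), nt, m)
    w = np.abs(vals)
    d = np.angle(vals)

    dead = w.sum(axis=(0, 1)) == 0.0

    # cumulative-sum initialisation from lag 1
    i1 = lags.index(1)
    phi = np.zeros((nt, m))
    phi[1:] = np.cumsum(-d[i1, : nt - 1], axis=0)

    n = nt - 1  # unknowns phi[1..nt-1]
    bw = max(lags)
    # normal-matrix structure is fixed; weights vary per pixel
    diag = np.zeros((n, m))
    off = np.zeros((bw, n, m))
    for li, lag in enumerate(lags):
        for t in range(nt - lag):
            a, b = t, t + lag  # pair (phi[a] - phi[b] = d)
            wtl = w[li, t]
            if a >= 1:
                diag[a - 1] += wtl
            diag[b - 1] += wtl
            if a >= 1:
                off[b - a - 1, a - 1] -= wtl
    diag += 1e-12 * (diag.max(axis=0, keepdims=True) + 1.0)
    factor = _cholesky_banded_factor_many(diag, off)

    for _ in range(max_iter):
        rhs = np.zeros((n, m))
        for li, lag in enumerate(lags):
            r = wrap_phase(phi[: nt - lag] - phi[lag:] - d[li, : nt - lag])
            wr = w[li, : nt - lag] * r
            # accumulate -J^T W r ; J row has +1 at a=t, -1 at b=t+lag
            rhs[lag - 1 :] += wr  # contribution to unknowns b-1 = t+lag-1
            rhs[: nt - 1 - lag] -= wr[1:]  # contribution to a-1 = t-1 (t>=1)
        delta = _cholesky_banded_solve_many(factor, rhs)
        phi[1:] += delta
        if np.max(np.abs(delta)) < tol:
            break

    # quality: weighted mean wrapped residual magnitude
    num = np.zeros(m)
    den = np.zeros(m)
    for li, lag in enumerate(lags):
        r = np.abs(wrap_phase(phi[: nt - lag] - phi[lag:] - d[li, : nt - lag]))
        num += (w[li, : nt - lag] * r).sum(axis=0)
        den += w[li, : nt - lag].sum(axis=0)
    quality = num / np.maximum(den, 1e-300)

    phi[:, dead] = np.nan
    quality[dead] = np.nan
    return PhaseMapSeries(phi.reshape((nt,) + spatial), quality.reshape(spatial), lags)


def phase_to_opl(phi: PhaseMapSeries, lambda0: float) -> OPLMapSeries:
    """Convert phase to optical path length, ``dl = phi * lambda0 / (4 pi)``.

    The factor assumes double-pass reflection geometry (light traverses the
    changed path twice), the standard convention for axial displacement in
    OCT.  An increase of the first band's path relative to the second is
    positive.
    """
    if lambda0 <= 0:
        raise ValueError("lambda0 must be positive")
    return OPLMapSeries(phi.phi * lambda0 / (4.0 * np.pi), lambda0)


def sublayer_series(
    volumes: np.ndarray,
    target_plane: int,
    lambda0: float,
    bands: Mapping[str, LayerBand] = DEFAULT_BANDS,
    lags: Sequence[int] = DEFAULT_LAGS,
    sigma: float = ENSEMBLE_SIGMA,
) -> Dict[str, OPLMapSeries]:
    """Per-sub-layer OPL time series of a flattened volume series.

    For each band in ``bands`` other than ``reference``, computes the paired
    cross-spectrum against the common reference band, ensemble-averages it
    laterally, solves the consistent phase and converts to OPL.
    """
    if "reference" not in bands:
        raise ValueError("band set must contain a 'reference' band")
    ref = bands["reference"]
    out: Dict[str, OPLMapSeries] = {}
    for name, band in bands.items():
        if name == "reference":
            continue
        dU = band_pair_cross_spectrum(volumes, band, ref, target_plane, lags)
        dU = ensemble_average(dU, sigma)
        phi = solve_phase(dU)
        out[name] = phase_to_opl(phi, lambda0)
    return out
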