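"""Inter-volume motion compensation by blockwise correlation.

Heart-beat induced pulsatile motion displaces the retina between volumes,
predominantly along the axis.  Registration estimates, for every volume, a
coarse grid of 3-D displacements from the cross-correlation of intensity
sub-volumes against a fixed reference volume, interpolates a dense
displacement field, and resamples the complex volume.  The axial component is
applied with the Fourier shift theorem so the interferometric phase rides
rigidly with the structure; the common bulk phase induced by axial motion is
not (and need not be) removed here — it cancels in the later differential
band pairing.

Registration is pairwise against one reference volume (the first baseline
volume by default) rather than chained, to avoid drift accumulation.
Correlating intensities (|U|^2) rather than complex fields keeps the shift
estimate robust against speckle decorrelation, which destroys complex
correlation long before it degrades the structural layer profile.
"""

from __future__ import annotations

import dataclasses
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage
from scipy.interpolate import RegularGridInterpolator

from ._util import axial_fourier_shift


class RegistrationError(RuntimeError):
    """Raised when a volume pair yields no valid block correlation."""


@dataclasses.dataclass
class DisplacementField:
    """Blockwise 3-D displacements of a moving volume vs. a reference.

    ``shifts[..., c]`` is the (z, y, x) displacement in voxels (fractional)
    at each block; ``confidence`` is the normalised correlation peak in
    [0, 1]; ``valid`` marks blocks whose confidence cleared the threshold.
    ``centers`` are the block-centre coordinates per axis.
    """

    shifts: np.ndarray  # (nbz, nby, nbx, 3)
    confidence: np.ndarray  # (nbz, nby, nbx)
    valid: np.ndarray  # bool, same shape as confidence
    centers: Tuple[np.ndarray, np.ndarray, np.ndarray]
    volume_shape: Tuple[int, int, int]

    def __post_init__(self):
        if not np.isfinite(self.shifts[self.valid]).all():
            raise ValueError("valid shifts must be finite")
        if ((self.confidence < 0) | (self.confidence > 1)).any():
            raise ValueError("confidence must lie in [0, 1]")

    def median_shift(self) -> np.ndarray:
        """Median (z, y, x) shift over valid blocks; NaN if none valid."""
        if not self.valid.any():
            return np.full(3, np.nan)
        return np.median(self.shifts[self.valid], axis=0)


def _block_starts(n: int, b: int, overlap: float) -> np.ndarray:
    if b > n:
        raise ValueError(f"block size {b} exceeds axis length {n}")
    step = max(1, int(round(b * (1.0 - overlap))))
    num = max(1, int(np.ceil((n - b) / step)) + 1)
    return np.unique(np.round(np.linspace(0, n - b, num)).astype(int))


def _parabolic_offset(cm: float, c0: float, cp: float) -> float:
    denom = cm - 2.0 * c0 + cp
    if denom >= 0 or abs(denom) < 1e-30:
        return 0.0
    return float(np.clip(0.5 * (cm - cp) / denom, -1.0, 1.0))


def _zoomed_axial_offset(field_cross_power, peak, block_size, half=1.0, step=0.02):
    """Subvoxel axial refinement by a zoomed DFT along z through the peak.

    Evaluates |complex-field cross-correlation| on a fine axial grid
    (+-``half`` voxels around the integer peak, at the lateral integer lags
    of the peak).  The field cross-correlation of speckle is band-limited,
    so its interpolated magnitude peaks at the true subvoxel shift; the
    *intensity* correlation cannot be used here — squaring doubles the
    speckle bandwidth, and the aliased correlation samples interpolate to a
    peak biased toward integer lags.
    """
    nz = block_size[0]
    ky = np.fft.fftfreq(block_size[1])[:, None]
    kx = np.fft.fftfreq(block_size[2])[None, :]
    phase = np.exp(2j * np.pi * (ky * peak[1] + kx * peak[2]))
    g = (field_cross_power * phase[None]).sum(axis=(1, 2))
    kz = np.fft.fftfreq(nz)
    s = np.arange(-half, half + step / 2, step) + peak[0]
    vals = np.abs((g[None, :] * np.exp(2j * np.pi * kz[None, :] * s[:, None])).sum(axis=1))
    return float(s[np.argmax(vals)] - peak[0])


def estimate_block_shifts(
    moving: np.ndarray,
    reference: np.ndarray,
    block_size: Tuple[int, int, int] = (32, 64, 64),
    overlap: float = 0.0,
    confidence_threshold: float = 0.1,
    max_shift: Optional[Tuple[int, int, int]] = None,
    _ref_prep: Optional[dict] = None,
) -> DisplacementField:
    """Per-block 3-D shift of ``moving`` relative to ``reference``.

    For each sub-volume, the circular cross-correlation of the mean-removed
    intensities is evaluated by FFT; the integer peak (restricted to
    ``max_shift``) is refined to subvoxel precision by a separable quadratic
    fit around the peak.  The confidence of a block is its normalised
    correlation coefficient at the peak; blocks below
    ``confidence_threshold`` are marked invalid.

    Raises :class:`RegistrationError` if no block is valid (unregisterable
    pair).
    """
    moving = np.asarray(moving)
    reference = np.asarray(reference)
    if moving.shape != reference.shape:
        raise ValueError("volumes must have the same shape")
    if min(block_size) < 8:
        raise ValueError("block_size must be >= 8 voxels per axis")
    shape = moving.shape
    if max_shift is None:
        max_shift = tuple(max(2, s // 4) for s in block_size)

    im = np.abs(moving).astype(np.float64) ** 2
    if _ref_prep is not None:
        ir = None
    else:
        ir = np.abs(reference).astype(np.float64) ** 2

    starts = [_block_starts(n, b, overlap) for n, b in zip(shape, block_size)]
    nb = tuple(len(s) for s in starts)
    shifts = np.zeros(nb + (3,))
    conf = np.zeros(nb)

    # wrap-aware signed lag coordinate per axis, and the allowed search mask
    lag = [np.fft.fftfreq(b) * b for b in block_size]
    allowed = (
        (np.abs(lag[0])[:, None, None] <= max_shift[0])
        & (np.abs(lag[1])[None, :, None] <= max_shift[1])
        & (np.abs(lag[2])[None, None, :] <= max_shift[2])
    )

    n_vox = float(np.prod(block_size))
    for i, z0 in enumerate(starts[0]):
        for j, y0 in enumerate(starts[1]):
            for k, x0 in enumerate(starts[2]):
                sl = (
                    slice(z0, z0 + block_size[0]),
                    slice(y0, y0 + block_size[1]),
                    slice(x0, x0 + block_size[2]),
                )
                m = im[sl] - im[sl].mean()
                sm = m.std()
                if _ref_prep is not None:
                    r_fft_conj, sr, rc_fft_conj = _ref_prep[(i, j, k)]
                else:
                    r = ir[sl] - ir[sl].mean()
                    sr = r.std()
                    r_fft_conj = np.conj(np.fft.rfftn(r))
                    rc = reference[sl]
                    rc_fft_conj = np.conj(np.fft.fftn(rc - rc.mean()))
                if sm == 0.0 or sr == 0.0:
                    conf[i, j, k] = 0.0
                    continue
                cc = np.fft.irfftn(np.fft.rfftn(m) * r_fft_conj, s=block_size, axes=(0, 1, 2))
                cc_masked = np.where(allowed, cc, -np.inf)
                p = np.unravel_index(np.argmax(cc_masked), cc.shape)
                peak = cc[p]
                conf[i, j, k] = float(np.clip(peak / (n_vox * sm * sr), 0.0, 1.0))
                p_signed = np.array([lag[ax][p[ax]] for ax in range(3)])
                mc = moving[sl]
                field_cp = np.fft.fftn(mc - mc.mean()) * rc_fft_conj
                sub = np.empty(3)
                sub[0] = _zoomed_axial_offset(field_cp, p_signed, block_size)
                for ax in (1, 2):
                    pm = list(p)
                    pp = list(p)
                    pm[ax] = (p[ax] - 1) % block_size[ax]
                    pp[ax] = (p[ax] + 1) % block_size[ax]
                    sub[ax] = _parabolic_offset(cc[tuple(pm)], peak, cc[tuple(pp)])
                shifts[i, j, k] = p_signed + sub

    valid = conf >= confidence_threshold
    if not valid.any():
        raise RegistrationError("no block cleared the confidence threshold")
    centers = tuple(
        s.astype(float) + (b - 1) / 2.0 for s, b in zip(starts, block_size)
    )
    return DisplacementField(shifts, conf, valid, centers, shape)


def _fill_invalid(field: DisplacementField) -> np.ndarray:
    """Block shifts with invalid blocks filled from their nearest valid one."""
    if not field.valid.any():
        raise RegistrationError("cannot densify a field with no valid block")
    shifts = field.shifts.copy()
    if not field.valid.all():
        grid = np.stack(
            np.meshgrid(*field.centers, indexing="ij"), axis=-1
        ).reshape(-1, 3)
        flat_valid = field.valid.ravel()
        from scipy.spatial import cKDTree

        tree = cKDTree(grid[flat_valid])
        _, nearest = tree.query(grid[~flat_valid])
        flat = shifts.reshape(-1, 3)
        flat[~flat_valid] = flat[flat_valid][nearest]
        shifts = flat.reshape(field.shifts.shape)
    return shifts


def densify_field(field: DisplacementField, target_shape=None) -> np.ndarray:
    """Interpolate block shifts to a dense per-voxel displacement field.

    Trilinear interpolation between block centres with edge-value (nearest)
    extrapolation beyond them; invalid blocks are filled from their nearest
    valid neighbour before interpolation.  Returns an array of shape
    ``target_shape + (3,)``.
    """
    if target_shape is None:
        target_shape = field.volume_shape
    shifts = _fill_invalid(field)

    coords = [np.arange(n, dtype=float) for n in target_shape]
    # clamp queries into the block-centre hull -> constant extrapolation
    query = [np.clip(c, ctr[0], ctr[-1]) for c, ctr in zip(coords, field.centers)]
    dense = np.empty(tuple(target_shape) + (3,), dtype=np.float32)
    pts = np.meshgrid(*query, indexing="ij")
    pts = np.stack([p.ravel() for p in pts], axis=-1)
    for c in range(3):
        vals = shifts[..., c]
        singleton = [len(ctr) == 1 for ctr in field.centers]
        if any(singleton):
            # RegularGridInterpolator needs >= 2 points per axis; collapse
            # singleton axes to constants
            keep = [i for i, s in enumerate(singleton) if not s]
            if not keep:
                dense[..., c] = vals.ravel()[0]
                continue
            sq = vals.reshape([len(ctr) for ctr in field.centers])
            sq = sq.reshape([n for n, s in zip(sq.shape, singleton) if not s])
            rgi = RegularGridInterpolator(
                [field.centers[i] for i in keep], sq, bounds_error=False, fill_value=None
            )
            dense[..., c] = rgi(pts[:, keep]).reshape(target_shape)
        else:
            rgi = RegularGridInterpolator(
                field.centers, vals, bounds_error=False, fill_value=None
            )
            dense[..., c] = rgi(pts).reshape(target_shape)
    return dense


def _apply_shift_maps(volume, axial, sy, sx):
    """Resample by per-A-scan shift maps (axial Fourier, lateral linear)."""
    nz = volume.shape[0]
    out = volume
    # lateral components below a twentieth of a voxel are subvoxel-fit noise;
    # resampling for them would only blur the speckle
    if max(np.abs(sy).max(), np.abs(sx).max()) > 0.05:
        yy, xx = np.meshgrid(
            np.arange(volume.shape[1], dtype=float),
            np.arange(volume.shape[2], dtype=float),
            indexing="ij",
        )
        coords = np.stack([yy - sy, xx - sx])
        res = np.empty_like(volume)
        for z in range(nz):
            re = ndimage.map_coordinates(out[z].real, coords, order=1, mode="nearest")
            imp = ndimage.map_coordinates(out[z].imag, coords, order=1, mode="nearest")
            res[z] = re + 1j * imp
        out = res
    if np.abs(axial).max() > 0:
        out = axial_fourier_shift(out, axial)
    return out.astype(volume.dtype)


def apply_displacement(volume: np.ndarray, dense_field: np.ndarray) -> np.ndarray:
    """Resample a complex volume by a dense displacement field.

    The axial component is applied as a per-A-scan subvoxel Fourier phase
    ramp (exact for band-limited content and phase-preserving for a static
    scatterer under pure axial motion); lateral components are applied by
    linear complex-valued interpolation.  Smooth fields are assumed: the
    shift of an A-scan is the depth-mean of the field over that A-scan.
    """
    volume = np.asarray(volume)
    dense_field = np.asarray(dense_field)
    if dense_field.shape[:3] != volume.shape or dense_field.shape[3] != 3:
        raise ValueError("dense field shape must be volume shape + (3,)")
    if np.abs(dense_field[..., 0]).max() > volume.shape[0] / 4:
        raise ValueError("axial displacement exceeds nz/4")
    axial = dense_field[..., 0].mean(axis=0)
    sy = dense_field[..., 1].mean(axis=0)
    sx = dense_field[..., 2].mean(axis=0)
    return _apply_shift_maps(volume, axial, sy, sx)


def lateral_shift_maps(field: DisplacementField) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-A-scan (axial, y, x) shift maps from a blockwise field.

    Depth-averages the (neighbour-filled) block shifts and interpolates them
    bilinearly over the lateral grid — the depth mean of the trilinear dense
    field, computed without materialising it.
    """
    ny, nx = field.volume_shape[1:]
    shifts = _fill_invalid(field)
    zmean = shifts.mean(axis=0)  # (nby, nbx, 3)
    cy, cx = field.centers[1], field.centers[2]
    yq = np.clip(np.arange(ny, dtype=float), cy[0], cy[-1])
    xq = np.clip(np.arange(nx, dtype=float), cx[0], cx[-1])
    maps = []
    for c in range(3):
        vals = zmean[..., c]
        if len(cy) == 1 and len(cx) == 1:
            maps.append(np.full((ny, nx), vals[0, 0]))
            continue
        if len(cy) == 1:
            maps.append(np.broadcast_to(np.interp(xq, cx, vals[0]), (ny, nx)).copy())
            continue
        if len(cx) == 1:
            maps.append(
                np.broadcast_to(np.interp(yq, cy, vals[:, 0])[:, None], (ny, nx)).copy()
            )
            continue
        rgi = RegularGridInterpolator((cy, cx), vals, bounds_error=False, fill_value=None)
        yy, xx = np.meshgrid(yq, xq, indexing="ij")
        maps.append(rgi(np.stack([yy.ravel(), xx.ravel()], axis=-1)).reshape(ny, nx))
    return maps[0], maps[1], maps[2]


def register_series(
    volumes: np.ndarray,
    reference_index: int = 0,
    block_size: Tuple[int, int, int] = (32, 64, 64),
    overlap: float = 0.0,
    confidence_threshold: float = 0.1,
) -> Tuple[np.ndarray, np.ndarray]:
    """Register a volume series to one reference volume.

    Returns the registered series and an (nt, 3) array of per-volume median
    shifts (for QC; the reference volume has an identically zero field).
    """
    volumes = np.asarray(volumes)
    nt = volumes.shape[0]
    registered = np.empty_like(volumes)
    med = np.zeros((nt, 3))
    ref = volumes[reference_index]

    # precompute reference block spectra once for the whole series
    ir = np.abs(ref).astype(np.float64) ** 2
    starts = [_block_starts(n, b, overlap) for n, b in zip(ref.shape, block_size)]
    ref_prep = {}
    for i, z0 in enumerate(starts[0]):
        for j, y0 in enumerate(starts[1]):
            for k, x0 in enumerate(starts[2]):
                sl = (
                    slice(z0, z0 + block_size[0]),
                    slice(y0, y0 + block_size[1]),
                    slice(x0, x0 + block_size[2]),
                )
                r = ir[sl] - ir[sl].mean()
                rc = ref[sl]
                ref_prep[(i, j, k)] = (
                    np.conj(np.fft.rfftn(r)),
                    r.std(),
                    np.conj(np.fft.fftn(rc - rc.mean())),
                )

    for t in range(nt):
        if t == reference_index:
            registered[t] = ref
            continue
        field = estimate_block_shifts(
            volumes[t], ref, block_size, overlap, confidence_threshold,
            _ref_prep=ref_prep,
        )
        axial, sy, sx = lateral_shift_maps(field)
        if np.abs(axial).max() > volumes.shape[1] / 4:
            raise RegistrationError("estimated axial displacement exceeds nz/4")
        registered[t] = _apply_shift_maps(volumes[t], -axial, -sy, -sx)
        med[t] = field.median_shift()
    return registered, med
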