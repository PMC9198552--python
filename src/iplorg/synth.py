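"""Seeded synthetic FF-SS-OCT measurement sequences with known ground truth.

This module emulates the raw material of a phase-sensitive optoretinography
experiment on the inner plexiform layer (IPL): a time series of complex-valued
OCT volumes of a layered retina, carrying

* fully developed speckle (circular complex Gaussian voxels scaled by a
  per-layer reflectivity),
* per-layer temporal speckle decorrelation (AR(1) evolution of the complex
  field, faster in the metabolically active inner retina),
* bulk axial motion (pulsatile sinusoid plus drift, applied as a Fourier
  voxel shift together with the corresponding common interferometric phase),
* and stimulus-evoked, nanometre-scale optical-path-length (OPL) changes
  stratified over three IPL sub-layers, with centre-surround edge
  enhancement, a saturating temporal rise, and a band-pass flicker tuning of
  the central sub-layer.

Every draw descends from a single integer master seed, so a dataset is fully
reproducible, and the injected OPL dynamics are returned as ground truth so
that the downstream registration / segmentation / phase pipeline can be
validated by parameter recovery.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy import ndimage, optimize

from ._util import axial_fourier_shift, child_rng
from .phase import ENSEMBLE_SIGMA

# ---------------------------------------------------------------------------
# system configuration
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class SystemConfig:
    """Acquisition geometry and timing of the full-field swept-source OCT.

    Defaults correspond to a 51 nm sweep centred at 841 nm, a 60 kHz camera
    acquiring 512 frames per volume sweep, and volumes triggered every 125 ms
    (8 Hz) — with a desk-scale voxel grid instead of the full-size
    640 x 368 x 512 sensor format (the physics is grid-size independent and a
    full-size series of 70 volumes would occupy tens of gigabytes).
    """

    lambda0: float = 841e-9  # centre wavelength (m)
    delta_lambda: float = 51e-9  # sweep bandwidth (m)
    frame_rate: float = 60000.0  # camera frame rate (Hz)
    frames_per_volume: int = 512
    volume_period: float = 0.125  # trigger interval (s)
    nx: int = 160
    ny: int = 128
    nz: int = 64
    dx: float = 4e-6  # lateral pitch (m)
    dy: float = 4e-6
    dz: float = 3.5e-6  # axial pitch (m); ~2.4x oversampling of the PSF

    def __post_init__(self):
        if self.lambda0 <= 0 or self.delta_lambda <= 0:
            raise ValueError("wavelengths must be positive")
        if 1.0 / self.volume_period > self.frame_rate / self.frames_per_volume:
            raise ValueError("volume trigger rate exceeds full-duty volume rate")
        if min(self.nx, self.ny, self.nz) < 8:
            raise ValueError("grid counts must be >= 8")

    @property
    def axial_resolution(self) -> float:
        """Axial FWHM resolution in air (m) of the rectangular sweep.

        The coherence PSF of a rectangular spectrum is a sinc^2 whose full
        width at half maximum is 0.6034 * lambda0^2 / delta_lambda.
        """
        return 0.6034 * self.lambda0**2 / self.delta_lambda

    @property
    def full_duty_volume_rate(self) -> float:
        """Volume rate (Hz) if sweeps ran back to back."""
        return self.frame_rate / self.frames_per_volume

    @property
    def volume_rate(self) -> float:
        """Triggered volume rate (Hz)."""
        return 1.0 / self.volume_period

    def times(self, n_volumes: int) -> np.ndarray:
        return np.arange(n_volumes) * self.volume_period

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self))

    @classmethod
    def from_json(cls, s: str) -> "SystemConfig":
        return cls(**json.loads(s))


# ---------------------------------------------------------------------------
# stimulus protocol
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class StimulusProtocol:
    """Visual stimulation pattern and timing.

    ``pattern`` is a binary (ny, nx) mask of illuminated pixels; ``None``
    selects the default centred square (see :func:`default_pattern`).
    Stimulation starts at ``onset_volume`` (zero-based; the default 4 leaves
    volumes 0-3 as baseline) and continues for ``duration`` seconds.  Flicker
    is a square wave with duty cycle 0.5, so a flicker stimulus delivers half
    the photons of a continuous one of equal duration and irradiance.
    """

    pattern: Optional[np.ndarray] = None
    waveform: str = "continuous"  # or "flicker"
    frequency: float = 0.0  # flicker rate (Hz)
    onset_volume: int = 4
    duration: float = 8.0

    def __post_init__(self):
        if self.waveform not in ("continuous", "flicker"):
            raise ValueError("waveform must be 'continuous' or 'flicker'")
        if self.waveform == "flicker" and self.frequency <= 0:
            raise ValueError("flicker requires frequency > 0")
        if self.onset_volume < 1:
            raise ValueError("onset_volume must be >= 1")
        if self.pattern is not None:
            p = np.asarray(self.pattern)
            if not np.isin(p, (0, 1)).all():
                raise ValueError("pattern values must be 0 or 1")
            self.pattern = p.astype(np.uint8)

    @property
    def photon_dose_factor(self) -> float:
        """Photon count relative to continuous stimulation of equal duration."""
        return 0.5 if self.waveform == "flicker" else 1.0

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["pattern"] = None if self.pattern is None else self.pattern.tolist()
        return json.dumps(d)

    @classmethod
    def from_json(cls, s: str) -> "StimulusProtocol":
        d = json.loads(s)
        if d["pattern"] is not None:
            d["pattern"] = np.asarray(d["pattern"], dtype=np.uint8)
        return cls(**d)


def default_pattern(config: SystemConfig, fraction: float = 0.35) -> np.ndarray:
    """Centred square stimulation pattern.

    The side is ``fraction * nx`` pixels; at the full sensor format
    (640 px, 4 um pitch) that is ~0.9 mm, matching the 1 mm x 1 mm projected
    square, and it scales with desk-size grids so that an unstimulated
    background region >= 200 um from the square always remains in the field.
    """
    side = int(round(fraction * config.nx))
    pat = np.zeros((config.ny, config.nx), dtype=np.uint8)
    y0 = (config.ny - side) // 2
    x0 = (config.nx - side) // 2
    pat[y0 : y0 + side, x0 : x0 + side] = 1
    return pat


# ---------------------------------------------------------------------------
# retina phantom
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class RetinaPhantom:
    """Layered reflectivity phantom with a curved, segmentable IPL lower edge.

    ``layer_boundaries`` are (ny, nx) depth maps (voxels, fractional allowed)
    separating ``len(boundaries) + 1`` layers, strictly increasing in depth at
    every lateral position.  ``ipl_lower_edge`` is the boundary used as
    segmentation ground truth.
    """

    layer_boundaries: List[np.ndarray]
    layer_reflectivities: List[float]
    decorrelation_times: List[float]
    ipl_lower_edge: np.ndarray

    def __post_init__(self):
        nb = len(self.layer_boundaries)
        if len(self.layer_reflectivities) != nb + 1:
            raise ValueError("need one reflectivity per layer (boundaries + 1)")
        if len(self.decorrelation_times) != nb + 1:
            raise ValueError("need one decorrelation time per layer")
        if any(r < 0 for r in self.layer_reflectivities):
            raise ValueError("reflectivities must be >= 0")
        if any(t <= 0 for t in self.decorrelation_times):
            raise ValueError("decorrelation times must be > 0")
        for a, b in zip(self.layer_boundaries[:-1], self.layer_boundaries[1:]):
            if not (np.asarray(b) > np.asarray(a)).all():
                raise ValueError("boundaries must be strictly increasing in depth")

    def reflectivity_volume(self, config: SystemConfig) -> np.ndarray:
        """Per-voxel mean backscatter amplitude with partial-volume blending."""
        z = np.arange(config.nz, dtype=float)[:, None, None]
        refl = np.full((config.nz, config.ny, config.nx), self.layer_reflectivities[0])
        for b, (r_lo, r_hi) in zip(
            self.layer_boundaries,
            zip(self.layer_reflectivities[:-1], self.layer_reflectivities[1:]),
        ):
            cover = np.clip(z + 0.5 - np.asarray(b)[None], 0.0, 1.0)
            refl = refl + (r_hi - r_lo) * cover
        return refl

    def tau_volume(self, config: SystemConfig) -> np.ndarray:
        """Per-voxel speckle decorrelation time (s)."""
        z = np.arange(config.nz, dtype=float)[:, None, None]
        tau = np.full((config.nz, config.ny, config.nx), self.decorrelation_times[0])
        for b, (t_lo, t_hi) in zip(
            self.layer_boundaries,
            zip(self.decorrelation_times[:-1], self.decorrelation_times[1:]),
        ):
            tau = tau + (t_hi - t_lo) * (z >= np.asarray(b)[None])
        return tau


def default_surface(config: SystemConfig) -> np.ndarray:
    """Smooth curved IPL lower edge: tilt plus gentle lateral undulation."""
    x = np.arange(config.nx)[None, :]
    y = np.arange(config.ny)[:, None]
    s = (
        0.55 * config.nz
        + 1.2 * np.sin(2 * np.pi * x / config.nx + 0.4)
        + 0.8 * np.sin(2 * np.pi * y / config.ny + 1.1)
        + 0.5 * (x / config.nx - 0.5)
    )
    return s + np.zeros((config.ny, config.nx))


def default_phantom(config: SystemConfig) -> RetinaPhantom:
    """Five-layer inner-retina phantom.

    Layers (top to bottom): vitreous, NFL/GCL complex, IPL, INL, outer
    retina.  The vitreous/retina interface and the IPL lower edge are the two
    dominant axial-gradient interfaces, so gradient-point selection followed
    by depth-ordered cluster selection isolates the IPL edge.

    Decorrelation is fastest in the vitreous and faster in the inner retina
    than in the outer retina.  The absolute times are calibrated so that the
    phase random walk they induce leaves well under 1 nm standard deviation
    on the masked steady-state readouts at the desk-scale grid — the noise
    level the in-vivo measurements exhibit on their (20x larger) analysis
    masks.  A desk-scale field of view shrinks the ensemble the readout
    averages over, so matching the readout noise (rather than any per-voxel
    decorrelation rate, which is not reported) keeps the synthetic study
    conditions faithful to the real experiment's signal-to-noise regime.
    """
    s = default_surface(config)
    boundaries = [s - 16.0, s - 10.0, s, s + 5.0]
    reflectivities = [0.04, 0.55, 0.62, 0.25, 0.35]
    taus = [0.3, 100.0, 120.0, 160.0, 200.0]
    return RetinaPhantom(boundaries, reflectivities, taus, s)


# ---------------------------------------------------------------------------
# response model
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class ResponseModel:
    """Stimulus-evoked OPL response of the three IPL sub-layers.

    Steady-state amplitudes are calibrated to the reported in-vivo values:
    the inner sub-layer (ON pathway) rises to +15 nm in the pattern centre
    and ~25 nm at its edges (edge_gain = 25/15); the outer sub-layer (OFF
    pathway) *decreases*, magnitude unquantified in vivo — the -10 nm default
    is a placeholder; the central sub-layer responds only at pattern edges
    (~10 nm) under continuous stimulation and gains a full-field +15 nm
    centre response at its preferred flicker frequency.

    The centre-surround receptive field is a difference of Gaussians (DoG);
    ``dog_sigma_center``/``dog_sigma_surround`` are in metres.  The temporal
    band-pass of the central sub-layer is log-Gaussian in frequency,
    unit-normalised at ``tcsf_peak`` with log-width ``tcsf_bandwidth``;
    B(0) = 0 and B(50 Hz) < 1e-3 so continuous and 50 Hz stimulation evoke
    essentially no centre response there.
    """

    amp_inner: float = 15e-9
    amp_outer: float = -10e-9
    amp_central_edge: float = 10e-9
    amp_central_flicker: float = 15e-9
    edge_gain: float = 25.0 / 15.0
    dog_sigma_center: float = 10e-6
    dog_sigma_surround: float = 20e-6
    dog_w_center: float = 1.0
    dog_w_surround: float = 0.35  # nominal; per-pattern calibration overrides
    tau_rise: float = 2.0
    tcsf_peak: float = 13.0
    tcsf_bandwidth: float = 0.35
    outer_edge_enhancement: bool = False

    def __post_init__(self):
        if not (self.dog_sigma_surround > self.dog_sigma_center > 0):
            raise ValueError("need dog_sigma_surround > dog_sigma_center > 0")
        if not (self.dog_w_center > self.dog_w_surround >= 0):
            raise ValueError("need dog_w_center > dog_w_surround >= 0")

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self))

    @classmethod
    def from_json(cls, s: str) -> "ResponseModel":
        return cls(**json.loads(s))


def temporal_bandpass(frequency: float, model: ResponseModel) -> float:
    """Flicker tuning B(f) of the central sub-layer, B(tcsf_peak) = 1.

    Log-Gaussian in frequency; B(0) is defined as 0 (continuous stimulation
    evokes no central-centre response).
    """
    if frequency <= 0:
        return 0.0
    u = np.log(frequency / model.tcsf_peak)
    return float(np.exp(-(u**2) / (2.0 * model.tcsf_bandwidth**2)))


def temporal_response(
    t: np.ndarray, protocol: StimulusProtocol, model: ResponseModel
) -> Dict[str, np.ndarray]:
    """Unit response time courses per sub-layer component.

    Zero before stimulus onset, then a saturating exponential rise
    ``1 - exp(-(t - t_on)/tau_rise)``.  Components:

    - ``inner`` / ``outer``: frequency-independent (these sub-layers respond
      identically to continuous and flicker stimulation),
    - ``central_edge``: the central sub-layer's edge component, also
      frequency-independent,
    - ``central_center``: the central sub-layer's full-field component,
      scaled by the flicker band-pass B(f) (zero for continuous stimulation).
    """
    t = np.asarray(t, dtype=float)
    if protocol.onset_volume >= t.size:
        raise ValueError("stimulus onset after end of record")
    t_on = t[protocol.onset_volume]
    rise = np.where(t >= t_on, 1.0 - np.exp(-np.maximum(t - t_on, 0) / model.tau_rise), 0.0)
    b = temporal_bandpass(
        protocol.frequency if protocol.waveform == "flicker" else 0.0, model
    )
    return {
        "inner": rise,
        "outer": rise,
        "central_edge": rise,
        "central_center": b * rise,
    }


# ---------------------------------------------------------------------------
# spatial response fields
# ---------------------------------------------------------------------------


def _smooth(pattern: np.ndarray, sigma_px: float) -> np.ndarray:
    return ndimage.gaussian_filter(pattern.astype(float), sigma_px, mode="wrap")


def _interior_index(pattern: np.ndarray) -> Tuple[int, int]:
    """Lateral index deepest inside the stimulated region."""
    dist = ndimage.distance_transform_edt(pattern)
    return np.unravel_index(np.argmax(dist), pattern.shape)


def spatial_response_field(
    pattern: np.ndarray,
    model: ResponseModel,
    dx: float,
    edge_gain: Optional[float] = None,
    post_smooth_sigma: float = 0.0,
    normalize_masks: Optional[Dict[str, np.ndarray]] = None,
) -> np.ndarray:
    """Centre-surround (DoG) lateral gain map of the stimulation pattern.

    Returns ``w_c * (G_sc * pattern) - w_s * (G_ss * pattern)``, rescaled so
    that its value deep inside the stimulated region equals 1.  The surround
    weight is calibrated numerically so the edge-ridge enhancement equals
    ``edge_gain`` — measured, when ``post_smooth_sigma > 0``, on the field
    after an additional Gaussian blur of that width (the analysis pipeline
    ensemble-averages its phase maps with a sigma = 4 px circular Gaussian,
    so the generator calibrates its edge amplitude on the same smoothed scale
    at which responses are read out).  With ``normalize_masks`` given, the
    enhancement is the ratio of the smoothed field's edge-mask mean to its
    centre-mask mean (the readout the reported values refer to); otherwise it
    is the ridge maximum over the deep-interior value.  The field vanishes
    far outside the pattern.
    """
    pattern = np.asarray(pattern)
    if not np.isin(pattern, (0, 1)).all():
        raise ValueError("pattern must be binary")
    if edge_gain is None:
        edge_gain = model.edge_gain
    sc = model.dog_sigma_center / dx
    ss = model.dog_sigma_surround / dx
    gc = _smooth(pattern, sc)
    gs = _smooth(pattern, ss)
    iy, ix = _interior_index(pattern)

    def field(ws: float) -> np.ndarray:
        return model.dog_w_center * gc - ws * gs

    def ratio(ws: float) -> float:
        f = field(ws)
        if post_smooth_sigma > 0:
            fs = ndimage.gaussian_filter(f, post_smooth_sigma, mode="wrap")
        else:
            fs = f
        if normalize_masks is not None:
            return float(fs[normalize_masks["edge"]].mean() / fs[normalize_masks["center"]].mean())
        return float(fs.max() / f[iy, ix])

    if edge_gain <= 1.0 + 1e-12:
        ws = 0.0
    else:
        hi = 0.999 * model.dog_w_center * gc[iy, ix] / gs[iy, ix]
        ws = optimize.brentq(lambda w: ratio(w) - edge_gain, 0.0, hi, xtol=1e-10)
    f = field(ws)
    return f / f[iy, ix]


def edge_response_field(
    pattern: np.ndarray,
    model: ResponseModel,
    dx: float,
    post_smooth_sigma: float = 0.0,
) -> np.ndarray:
    """Pure edge (zero-interior) response field, unit peak.

    Balanced DoG: the surround weight is chosen so the field vanishes deep
    inside the pattern, leaving only the edge ridge; normalised so that the
    (optionally post-smoothed) ridge maximum is 1.  Models the central
    sub-layer's edge-only response to continuous stimulation.
    """
    pattern = np.asarray(pattern)
    if not np.isin(pattern, (0, 1)).all():
        raise ValueError("pattern must be binary")
    sc = model.dog_sigma_center / dx
    ss = model.dog_sigma_surround / dx
    gc = _smooth(pattern, sc)
    gs = _smooth(pattern, ss)
    iy, ix = _interior_index(pattern)
    f = gc - (gc[iy, ix] / gs[iy, ix]) * gs
    fm = f
    if post_smooth_sigma > 0:
        fm = ndimage.gaussian_filter(f, post_smooth_sigma, mode="wrap")
    return f / fm.max()


def analysis_mask_geometry(
    pattern: np.ndarray,
    model: ResponseModel,
    config: SystemConfig,
    interior_margin_px: int = 14,
    edge_threshold: float = 0.7,
    background_distance: float = 200e-6,
) -> Dict[str, np.ndarray]:
    """Canonical centre / edge / background analysis masks for a pattern.

    centre: pixels more than ``interior_margin_px`` inside the pattern (where
    the smoothed response has reached its interior plateau); edge: pixels
    where the ensemble-smoothed edge-response template exceeds
    ``edge_threshold`` of its ridge maximum (the ridge peaks a few pixels
    inside the outline because of the centre-surround geometry); background:
    pixels at least ``background_distance`` from any stimulated pixel.

    Defined here (rather than only in the response stage) because the
    generator calibrates its response fields against the very same masks: the
    reported in-vivo amplitudes are mask-averaged readouts, so the synthetic
    truth is normalised such that the standard readout reproduces them.
    """
    pattern_b = np.asarray(pattern).astype(bool)
    inside = ndimage.distance_transform_edt(pattern_b)
    center = inside >= interior_margin_px
    edge_template = edge_response_field(
        pattern_b.astype(np.uint8), model, config.dx, post_smooth_sigma=ENSEMBLE_SIGMA
    )
    smoothed = ndimage.gaussian_filter(edge_template, ENSEMBLE_SIGMA, mode="wrap")
    edge = (smoothed >= edge_threshold * smoothed.max()) & ~center
    outside = ndimage.distance_transform_edt(~pattern_b) * config.dx
    background = outside >= background_distance
    return {"center": center, "edge": edge, "background": background}


# ---------------------------------------------------------------------------
# ground truth container
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class GroundTruth:
    """What the generator injected, for parameter-recovery validation.

    ``opl`` maps band name -> (nt, ny, nx) OPL change in metres, exactly the
    differential phase (band vs. sub-IPL reference) embedded in the volumes.
    ``background`` is a laterally uniform OPL drift (vascular pulsation and
    metabolic motion of the inner retina against the reference) added on top
    of the functional fields in all three strata; the background correction
    of the response stage removes it exactly.  ``displacement`` is the
    applied bulk axial motion in voxels per volume.  Note the pipeline reads
    out its maps *after* a sigma = 4 px lateral ensemble average; compare
    against ``opl`` smoothed by the same kernel.
    """

    opl: Dict[str, np.ndarray]
    displacement: np.ndarray
    surface: np.ndarray
    pattern: np.ndarray
    background: Optional[np.ndarray] = None


# ---------------------------------------------------------------------------
# generator operations
# ---------------------------------------------------------------------------


def make_speckle_volume(
    phantom: RetinaPhantom, config: SystemConfig, seed: int
) -> np.ndarray:
    """One volume of fully developed speckle.

    Each voxel is a zero-mean circular complex Gaussian draw scaled by the
    local reflectivity r, i.e. Re, Im ~ N(0, r^2/2): magnitudes are Rayleigh
    with mean r sqrt(pi)/2, phases uniform on (-pi, pi].
    """
    refl = phantom.reflectivity_volume(config)
    rng = child_rng(seed, 0)
    shape = refl.shape
    u = rng.standard_normal(shape) + 1j * rng.standard_normal(shape)
    return (refl / np.sqrt(2.0) * u).astype(np.complex64)


def apply_decorrelation(
    volumes: np.ndarray, phantom: RetinaPhantom, config: SystemConfig, seed: int
) -> np.ndarray:
    """Evolve a volume series as per-voxel AR(1) complex Gaussian processes.

    Successive volumes correlate as ``exp(-dt_vol / tau)`` with the local
    layer's decorrelation time; innovations are fresh circular Gaussian draws
    scaled by the local reflectivity, so the marginal speckle statistics
    (Rayleigh magnitude, uniform phase) are preserved at every time step.
    The first volume is passed through unchanged.
    """
    volumes = np.asarray(volumes)
    refl = phantom.reflectivity_volume(config).astype(np.float32)
    tau = phantom.tau_volume(config)
    rho = np.exp(-config.volume_period / tau).astype(np.float32)
    innov_scale = (refl * np.sqrt((1.0 - rho.astype(np.float64) ** 2) / 2.0)).astype(
        np.float32
    )
    rng = child_rng(seed, 1)
    out = np.empty_like(volumes, dtype=np.complex64)
    out[0] = volumes[0]
    shape = volumes.shape[1:]
    for t in range(1, volumes.shape[0]):
        n = rng.standard_normal(shape, dtype=np.float32) + 1j * rng.standard_normal(
            shape, dtype=np.float32
        )
        out[t] = rho * out[t - 1] + innov_scale * n
    return out


def stratum_masks(
    config: SystemConfig, surface: np.ndarray
) -> Dict[str, np.ndarray]:
    """Boolean (z, y, x) masks of the three IPL sub-layer strata.

    Voxels at and above each sub-layer band carry that band's OPL relative to
    the static sub-edge reference.  Strata relative to the edge depth s:
    inner ``z - s <= -6``, central ``(-6, -3]``, outer ``(-3, +0.5]``, and
    zero phase below.  The boundaries sit at the centres of the gap voxels
    between the two-voxel measurement bands (offsets inner {-8,-7}, central
    {-5,-4}, outer {-2,-1}, reference {+2,+3}), leaving at least one voxel of
    guard margin so that the sinc tails of fractional axial resampling
    (registration, flattening) mix negligible phase across strata.
    """
    z = np.arange(config.nz, dtype=float)[:, None, None]
    zr = z - surface[None]
    return {
        "inner": zr <= -6.0,
        "central": (zr > -6.0) & (zr <= -3.0),
        "outer": (zr > -3.0) & (zr <= 0.5),
    }


def _stratum_opl_profile(
    config: SystemConfig, surface: np.ndarray, opl: Dict[str, np.ndarray], t: int
) -> np.ndarray:
    """Per-voxel OPL offset at time t from the per-band truth fields."""
    masks = stratum_masks(config, surface)
    dl = np.zeros((config.nz, config.ny, config.nx))
    for name, m in masks.items():
        dl += m * opl[name][t][None]
    return dl


def embed_opl_dynamics(
    volumes: np.ndarray, truth: GroundTruth, config: SystemConfig
) -> np.ndarray:
    """Imprint the ground-truth OPL dynamics as interferometric phase.

    Multiplies the voxels of each sub-layer stratum (and everything above the
    inner stratum) by ``exp(i 4 pi dl(x, y, t) / lambda0)`` so that the
    differential phase between each measurement band and the sub-edge
    reference band carries exactly the intended OPL; a noiseless, motionless
    round trip through the phase pipeline recovers ``dl`` to machine
    precision.  Warns if any per-volume-step OPL increment exceeds
    lambda0 / 8 (phase-wrap hazard at the lag-1 spacing).
    """
    for name in ("inner", "central", "outer"):
        step = np.abs(np.diff(truth.opl[name], axis=0)).max() if len(truth.opl[name]) > 1 else 0.0
        if step > config.lambda0 / 8.0:
            warnings.warn(
                f"{name} OPL step {step:.2e} m exceeds lambda0/8: phase may wrap"
            )
    out = np.empty_like(volumes, dtype=np.complex64)
    k = 4.0 * np.pi / config.lambda0
    masks = stratum_masks(config, truth.surface)
    m_inner, m_central, m_outer = masks["inner"], masks["central"], masks["outer"]
    bg = truth.background if truth.background is not None else np.zeros(volumes.shape[0])
    for t in range(volumes.shape[0]):
        e_in = np.exp(1j * k * (truth.opl["inner"][t] + bg[t])).astype(np.complex64)
        e_ce = np.exp(1j * k * (truth.opl["central"][t] + bg[t])).astype(np.complex64)
        e_ou = np.exp(1j * k * (truth.opl["outer"][t] + bg[t])).astype(np.complex64)
        p = np.where(
            m_inner, e_in[None], np.where(m_central, e_ce[None], np.where(m_outer, e_ou[None], np.complex64(1.0)))
        )
        out[t] = volumes[t] * p
    return out


@dataclasses.dataclass
class MotionParams:
    """Bulk axial motion: pulsatile sinusoid plus slow drift, in voxels.

    The course is anchored at zero for the first volume — displacement, like
    the phase, is only ever defined relative to the start of the record.
    """

    amplitude: float = 1.2  # voxels
    frequency: float = 1.17  # Hz, heart-beat-like
    drift: float = 0.6  # voxels over the record
    phase0: float = 0.0  # radians


def bulk_motion_course(
    t: np.ndarray, params: MotionParams = MotionParams()
) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    span = t[-1] if t[-1] > 0 else 1.0
    course = params.amplitude * np.sin(
        2 * np.pi * params.frequency * t + params.phase0
    ) + params.drift * t / span
    return course - course[0]


def apply_bulk_motion(
    volumes: np.ndarray,
    truth: GroundTruth,
    config: SystemConfig,
    params: MotionParams = MotionParams(),
) -> np.ndarray:
    """Apply smooth global axial displacement to every volume.

    Each volume is shifted along z by the Fourier shift theorem and
    multiplied by the corresponding common interferometric phase
    ``exp(i 4 pi m dz / lambda0)`` (which cancels later in the band-pairing
    but corrupts any single-layer phase, as vascular pulsation does in vivo).
    The course is recorded in ``truth.displacement``.
    """
    t = config.times(volumes.shape[0])
    m = bulk_motion_course(t, params)
    if np.abs(m).max() > config.nz / 4:
        raise ValueError("bulk displacement exceeds nz/4 voxels")
    out = np.empty_like(volumes, dtype=np.complex64)
    k = 4.0 * np.pi * config.dz / config.lambda0
    for i in range(volumes.shape[0]):
        if m[i] == 0.0:
            out[i] = volumes[i]
        else:
            shifted = axial_fourier_shift(volumes[i], m[i])
            out[i] = (shifted * np.exp(1j * k * m[i])).astype(np.complex64)
    truth.displacement = m
    return out


# ---------------------------------------------------------------------------
# dataset composition and serialisation
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class Dataset:
    """A generated measurement sequence with its ground truth and metadata."""

    volumes: np.ndarray  # (nt, nz, ny, nx) complex64
    truth: GroundTruth
    config: SystemConfig
    protocol: StimulusProtocol
    model: ResponseModel
    seed: int


@dataclasses.dataclass
class BackgroundParams:
    """Laterally uniform OPL background: pulsation plus slow metabolic drift."""

    pulse_amp: float = 4e-9  # m
    pulse_freq: float = 1.17  # Hz
    drift: float = 5e-9  # m over the record
    phase0: float = 0.9


def background_course(t: np.ndarray, params: BackgroundParams = BackgroundParams()):
    t = np.asarray(t, dtype=float)
    span = t[-1] if t[-1] > 0 else 1.0
    return params.pulse_amp * np.sin(
        2 * np.pi * params.pulse_freq * t + params.phase0
    ) + params.drift * t / span


def build_truth(
    config: SystemConfig,
    protocol: StimulusProtocol,
    model: ResponseModel,
    phantom: RetinaPhantom,
    n_volumes: int,
    background: Optional[BackgroundParams] = BackgroundParams(),
) -> GroundTruth:
    """Assemble the per-band OPL truth fields from the response model.

    The spatial fields are calibrated against the canonical analysis masks:
    the in-vivo amplitudes this generator reproduces (25/15/10/15 nm) are
    mask-averaged readouts of ensemble-smoothed phase maps, so each field is
    scaled such that the smoothed centre-mask (interior amplitudes) or
    edge-mask (edge amplitudes) mean equals the model amplitude.
    """
    pattern = protocol.pattern
    if pattern is None:
        pattern = default_pattern(config)
    if pattern.shape != (config.ny, config.nx):
        raise ValueError("pattern shape must match the lateral grid")
    t = config.times(n_volumes)
    courses = temporal_response(t, protocol, model)
    masks = analysis_mask_geometry(pattern, model, config)

    def smoothed_mask_mean(field, mask):
        return ndimage.gaussian_filter(field, ENSEMBLE_SIGMA, mode="wrap")[mask].mean()

    f_inner = spatial_response_field(
        pattern, model, config.dx, model.edge_gain,
        post_smooth_sigma=ENSEMBLE_SIGMA, normalize_masks=masks,
    )
    f_inner = f_inner / smoothed_mask_mean(f_inner, masks["center"])
    f_flat = spatial_response_field(
        pattern, model, config.dx, edge_gain=1.0, post_smooth_sigma=ENSEMBLE_SIGMA
    )
    f_flat = f_flat / smoothed_mask_mean(f_flat, masks["center"])
    f_outer = f_inner if model.outer_edge_enhancement else f_flat
    f_edge = edge_response_field(
        pattern, model, config.dx, post_smooth_sigma=ENSEMBLE_SIGMA
    )
    f_edge = f_edge / smoothed_mask_mean(f_edge, masks["edge"])
    opl = {
        "inner": model.amp_inner * courses["inner"][:, None, None] * f_inner[None],
        "outer": model.amp_outer * courses["outer"][:, None, None] * f_outer[None],
        "central": (
            model.amp_central_edge * courses["central_edge"][:, None, None] * f_edge[None]
            + model.amp_central_flicker
            * courses["central_center"][:, None, None]
            * f_flat[None]
        ),
    }
    if background is not None:
        bg = background_course(t, background)
        bg = bg - bg[0]  # phase is measured relative to the first volume
    else:
        bg = None
    return GroundTruth(
        opl=opl,
        displacement=np.zeros(n_volumes),
        surface=np.asarray(phantom.ipl_lower_edge, dtype=float),
        pattern=pattern,
        background=bg,
    )


def generate_dataset(
    config: SystemConfig = None,
    protocol: StimulusProtocol = None,
    phantom: RetinaPhantom = None,
    model: ResponseModel = None,
    seed: int = 0,
    n_volumes: int = 70,
    motion: Optional[MotionParams] = MotionParams(),
    background: Optional[BackgroundParams] = BackgroundParams(),
) -> Dataset:
    """Generate a complete seeded measurement sequence with ground truth.

    Composition order: static speckle -> AR(1) decorrelation -> OPL phase
    embedding -> bulk axial motion.  The storage budget of the in-vivo
    instrument restricted a sequence to ~70 volumes at 8 Hz; the same default
    is used here.
    """
    config = config or SystemConfig()
    protocol = protocol or StimulusProtocol()
    phantom = phantom or default_phantom(config)
    model = model or ResponseModel()

    truth = build_truth(config, protocol, model, phantom, n_volumes, background)
    base = make_speckle_volume(phantom, config, seed)
    series = np.broadcast_to(base, (n_volumes,) + base.shape)
    series = apply_decorrelation(series, phantom, config, seed)
    series = embed_opl_dynamics(series, truth, config)
    if motion is not None:
        series = apply_bulk_motion(series, truth, config, motion)
    return Dataset(series, truth, config, protocol, model, seed)


def save_dataset(ds: Dataset, path, manifest: bool = True) -> None:
    """Write a dataset to HDF5 (with a JSON sidecar manifest).

    Layout: ``/volumes`` (t, z, y, x complex), ``/truth/opl/<band>``,
    ``/truth/surface``, ``/truth/displacement``, ``/truth/pattern``; config,
    protocol and response model are stored as JSON attributes.
    """
    import h5py

    path = str(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("volumes", data=ds.volumes)
        g = f.create_group("truth")
        go = g.create_group("opl")
        for name, arr in ds.truth.opl.items():
            go.create_dataset(name, data=arr)
        g.create_dataset("surface", data=ds.truth.surface)
        g.create_dataset("displacement", data=ds.truth.displacement)
        g.create_dataset("pattern", data=ds.truth.pattern)
        if ds.truth.background is not None:
            g.create_dataset("background", data=ds.truth.background)
        f.attrs["config"] = ds.config.to_json()
        f.attrs["protocol"] = ds.protocol.to_json()
        f.attrs["model"] = ds.model.to_json()
        f.attrs["seed"] = ds.seed
    if manifest:
        with open(path + ".json", "w") as fh:
            json.dump({"seed": ds.seed, "format_version": 1, "file": path}, fh)


def load_dataset(path) -> Dataset:
    """Read a dataset written by :func:`save_dataset` (bit-identical arrays)."""
    import h5py

    with h5py.File(str(path), "r") as f:
        volumes = f["volumes"][()]
        opl = {k: f["truth/opl"][k][()] for k in f["truth/opl"]}
        truth = GroundTruth(
            opl=opl,
            displacement=f["truth/displacement"][()],
            surface=f["truth/surface"][()],
            pattern=f["truth/pattern"][()],
            background=f["truth/background"][()] if "truth/background" in f else None,
        )
        config = SystemConfig.from_json(f.attrs["config"])
        protocol = StimulusProtocol.from_json(f.attrs["protocol"])
        model = ResponseModel.from_json(f.attrs["model"])
        seed = int(f.attrs["seed"])
    return Dataset(volumes, truth, config, protocol, model, seed)
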