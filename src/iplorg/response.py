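"""Functional readouts: time courses, profiles, amplitudes, frequency tuning.

Converts per-band OPL map series into the quantities an optoretinography
experiment reports: background-corrected mean time courses over the
stimulated area, lateral edge/centre profiles, steady-state amplitudes
(mean over the last 625 ms of stimulation), and the flicker
frequency-response curve of the central IPL sub-layer.

Residual motion artefacts (vascular pulsation, metabolic drift) contaminate
the phase as a laterally common background; it is removed by subtracting,
per time point, the mean OPL over an unstimulated mask at a safe distance
(>= 200 um) from the stimulation site.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .phase import ENSEMBLE_SIGMA, OPLMapSeries
from .synth import ResponseModel, SystemConfig, analysis_mask_geometry


@dataclasses.dataclass
class MaskSet:
    """Analysis masks: stimulated centre, stimulated edge, background.

    The background mask lies entirely at least ``background_distance`` (in
    lateral metric units) from any stimulated pixel and is disjoint from the
    stimulus masks.
    """

    center: np.ndarray
    edge: np.ndarray
    background: np.ndarray
    background_distance: float = 200e-6

    def __post_init__(self):
        for name in ("center", "edge", "background"):
            setattr(self, name, np.asarray(getattr(self, name)).astype(bool))
        if (self.background & (self.center | self.edge)).any():
            raise ValueError("background mask overlaps a stimulus mask")
        if not self.background.any():
            raise ValueError("background mask is empty")


def make_masks(
    pattern: np.ndarray,
    model: ResponseModel,
    config: SystemConfig,
    interior_margin_px: int = 14,
    edge_threshold: float = 0.7,
    background_distance: float = 200e-6,
) -> MaskSet:
    """Derive analysis masks from the stimulation pattern.

    centre: pixels deeper than ``interior_margin_px`` inside the pattern
    (where the smoothed response field has reached its interior plateau);
    edge: pixels where the ensemble-smoothed edge-response template exceeds
    ``edge_threshold`` of its ridge maximum; background: pixels at least
    ``background_distance`` from any stimulated pixel.  (The in-vivo
    analysis drew the stimulus mask manually per measurement; deriving it
    from the known pattern automates the same intent for synthetic data.)
    """
    geo = analysis_mask_geometry(
        pattern, model, config, interior_margin_px, edge_threshold,
        background_distance,
    )
    return MaskSet(geo["center"], geo["edge"], geo["background"], background_distance)


def background_correct(opl: OPLMapSeries, masks: MaskSet) -> OPLMapSeries:
    """Subtract the background-mask mean from every pixel, per time point."""
    if not masks.background.any():
        raise ValueError("background mask is empty")
    bg = opl.opl[:, masks.background].mean(axis=1)
    return OPLMapSeries(opl.opl - bg[:, None, None], opl.lambda0)


def timecourse(
    opl: OPLMapSeries, mask: np.ndarray, baseline_volumes: int = 4
) -> np.ndarray:
    """Mean OPL over a mask vs. time, anchored to the pre-stimulus baseline.

    The mean of the first ``baseline_volumes`` volumes (the pre-stimulus
    baseline) is subtracted so the course starts at zero.
    """
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise ValueError("mask is empty")
    course = opl.opl[:, mask].mean(axis=1)
    if baseline_volumes > 0:
        course = course - course[:baseline_volumes].mean()
    return course


def profile(
    opl_map: np.ndarray, center_row: Optional[int] = None, averaging_width: int = 150
) -> np.ndarray:
    """Lateral OPL profile, vertically averaged over a strip of rows.

    Averages ``averaging_width`` rows centred on ``center_row`` (default the
    middle of the field) and returns OPL vs. horizontal position.
    """
    opl_map = np.asarray(opl_map)
    ny = opl_map.shape[0]
    if averaging_width > ny:
        raise ValueError("averaging width exceeds the field")
    if center_row is None:
        center_row = ny // 2
    lo = max(0, center_row - averaging_width // 2)
    hi = min(ny, lo + averaging_width)
    lo = hi - averaging_width
    return opl_map[lo:hi].mean(axis=0)


def steady_state(
    course: np.ndarray, volume_period: float, window: float = 0.625
) -> float:
    """Mean of the last ``window`` seconds of a time course.

    At the 8 Hz volume rate the default 625 ms window averages exactly the
    last 5 volumes, suppressing residual pulsation noise.
    """
    course = np.asarray(course, dtype=float)
    n = int(np.floor(window / volume_period))
    if n < 1:
        raise ValueError("window shorter than one volume period")
    if n > course.size:
        raise ValueError("window exceeds the record")
    return float(course[-n:].mean())


@dataclasses.dataclass
class ResponseCurve:
    """Flicker frequency-response curve of the central sub-layer.

    ``frequencies`` lists the tested conditions (0 denotes continuous
    stimulation); ``amplitudes[i]`` holds the individual steady-state
    measurements at ``frequencies[i]`` and ``mean_amplitudes`` their means.
    """

    frequencies: np.ndarray
    amplitudes: List[List[float]]
    mean_amplitudes: np.ndarray

    def __post_init__(self):
        if len(np.unique(self.frequencies)) != len(self.frequencies):
            raise ValueError("frequencies must be unique")

    @property
    def peak_frequency(self) -> float:
        """Tested frequency with the largest mean response."""
        return float(self.frequencies[int(np.argmax(self.mean_amplitudes))])

    @property
    def peak_amplitude(self) -> float:
        return float(np.max(self.mean_amplitudes))


#: Default stimulation-frequency grid (Hz; 0 = continuous): 11 flicker
#: frequencies spanning 1-55 Hz plus the continuous condition.
DEFAULT_FREQUENCIES = (0.0, 1.0, 2.0, 3.3, 5.0, 6.7, 10.0, 12.5, 16.6, 25.0, 33.0, 55.0)


def frequency_sweep(
    measurements: Sequence[Tuple[float, OPLMapSeries]],
    masks: MaskSet,
    config: SystemConfig,
    window: float = 0.625,
    n_reps: int = 2,
) -> ResponseCurve:
    """Frequency-response curve from per-condition central-band OPL series.

    Each measurement contributes the steady-state mean over the *centre*
    mask (edge responses are excluded: they do not vary with stimulation
    frequency); repeated measurements at one frequency are averaged.  Warns
    when a frequency has fewer than ``n_reps`` measurements.
    """
    if len(measurements) < 2:
        raise ValueError("need at least 2 frequencies")
    by_freq: Dict[float, List[float]] = {}
    for freq, opl in measurements:
        course = timecourse(opl, masks.center)
        amp = steady_state(course, config.volume_period, window)
        by_freq.setdefault(float(freq), []).append(amp)
    freqs = np.array(sorted(by_freq))
    amps = [by_freq[f] for f in freqs]
    for f, a in zip(freqs, amps):
        if len(a) < n_reps:
            warnings.warn(f"frequency {f} Hz has {len(a)} of {n_reps} measurements")
    means = np.array([np.mean(a) for a in amps])
    return ResponseCurve(freqs, amps, means)
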