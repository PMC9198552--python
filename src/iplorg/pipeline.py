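"""End-to-end analysis: register -> segment -> flatten -> phase -> response.

Glue for running the whole evaluation on a generated (or loaded) dataset and
for the flicker frequency-sweep experiment.  Each stage is the corresponding
module's public API; this module only sequences them and collects results.
"""

from __future__ import annotations

import dataclasses
from typing import Dict, Optional, Sequence, Tuple

import numpy as np

from . import phase as phase_mod
from . import register as register_mod
from . import response as response_mod
from . import segment as segment_mod
from . import synth as synth_mod


@dataclasses.dataclass
class PipelineResult:
    """Everything the analysis produces for one measurement sequence."""

    surface: segment_mod.LayerSurface
    target_plane: int
    shifts: np.ndarray  # (nt, 3) per-volume median registration shifts
    opl: Dict[str, phase_mod.OPLMapSeries]  # background-corrected, per band
    masks: response_mod.MaskSet
    timecourses: Dict[str, Dict[str, np.ndarray]]  # band -> mask -> course
    steady: Dict[str, Dict[str, float]]  # band -> mask -> metres


def run_pipeline(
    dataset: synth_mod.Dataset,
    bands=phase_mod.DEFAULT_BANDS,
    lags: Sequence[int] = phase_mod.DEFAULT_LAGS,
    sigma: float = phase_mod.ENSEMBLE_SIGMA,
    register: bool = True,
    masks: Optional[response_mod.MaskSet] = None,
    background_distance: float = 200e-6,
    surface: Optional[segment_mod.LayerSurface] = None,
) -> PipelineResult:
    """Run the full analysis on one dataset.

    Registration is against the first baseline volume; segmentation runs
    once on the time-averaged registered intensity and is reused for all
    volumes; flattening, band pairing, ensemble averaging, consistent-phase
    solving and background correction follow.
    """
    cfg = dataset.config
    if register:
        registered, shifts = register_mod.register_series(dataset.volumes)
    else:
        registered, shifts = dataset.volumes, np.zeros((dataset.volumes.shape[0], 3))

    if surface is None:
        mean_intensity = np.mean(np.abs(registered) ** 2, axis=0)
        surface = segment_mod.segment_ipl_edge(np.sqrt(mean_intensity))

    # flatten in place (the unflattened registered series is not needed any
    # more); rigid whole-voxel flattening so band voxels sample pure
    # single-layer content instead of sinc-interpolated mixtures
    flattened = registered if register else registered.copy()
    target_plane = int(round(float(np.median(surface.depth))))
    for t in range(flattened.shape[0]):
        flattened[t], _ = segment_mod.flatten_volume(
            flattened[t], surface, target_plane, subvoxel=False
        )

    opl_raw = phase_mod.sublayer_series(
        flattened, target_plane, cfg.lambda0, bands=bands, lags=lags, sigma=sigma
    )

    if masks is None:
        masks = response_mod.make_masks(
            dataset.truth.pattern, dataset.model, cfg,
            background_distance=background_distance,
        )
    opl = {k: response_mod.background_correct(v, masks) for k, v in opl_raw.items()}

    mask_map = {"center": masks.center, "edge": masks.edge}
    courses = {
        band: {
            mname: response_mod.timecourse(series, m)
            for mname, m in mask_map.items()
        }
        for band, series in opl.items()
    }
    steady = {
        band: {
            mname: response_mod.steady_state(c, cfg.volume_period)
            for mname, c in per_mask.items()
        }
        for band, per_mask in courses.items()
    }
    return PipelineResult(surface, target_plane, shifts, opl, masks, courses, steady)


def sweep_experiment(
    seed: int,
    frequencies: Sequence[float] = response_mod.DEFAULT_FREQUENCIES,
    config: Optional[synth_mod.SystemConfig] = None,
    model: Optional[synth_mod.ResponseModel] = None,
    n_volumes: int = 70,
    n_reps: int = 1,
    background_distance: float = 200e-6,
) -> Tuple[response_mod.ResponseCurve, Dict[float, Dict[str, Dict[str, float]]]]:
    """Generate and analyse one dataset per stimulation frequency.

    ``frequencies`` uses 0 for the continuous condition.  Each condition gets
    its own seeded dataset (seed derived from the master seed, the condition
    index and the repetition index) and a full pipeline pass; the central
    band's centre-mask steady state enters the response curve.  Returns the
    curve and, per frequency, the last replicate's steady-state summary
    (band -> mask -> metres); full map series are not retained, so a sweep's
    memory footprint stays at a single dataset.
    """
    import gc

    config = config or synth_mod.SystemConfig()
    model = model or synth_mod.ResponseModel()
    by_freq: Dict[float, list] = {}
    steady: Dict[float, Dict[str, Dict[str, float]]] = {}
    for i, f in enumerate(frequencies):
        for rep in range(n_reps):
            if f <= 0:
                protocol = synth_mod.StimulusProtocol(waveform="continuous")
            else:
                protocol = synth_mod.StimulusProtocol(waveform="flicker", frequency=f)
            ds = synth_mod.generate_dataset(
                config=config,
                protocol=protocol,
                model=model,
                seed=(int(seed) * 1000 + i * 10 + rep) % (2**31 - 1),
                n_volumes=n_volumes,
            )
            res = run_pipeline(ds, background_distance=background_distance)
            amp = response_mod.steady_state(
                res.timecourses["central"]["center"], config.volume_period
            )
            by_freq.setdefault(float(f), []).append(amp)
            steady[float(f)] = res.steady
            # a full-size volume series per condition: release before the next
            del ds, res
            gc.collect()
    freqs = np.array(sorted(by_freq))
    amps = [by_freq[f] for f in freqs]
    curve = response_mod.ResponseCurve(
        freqs, amps, np.array([np.mean(a) for a in amps])
    )
    return curve, steady
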