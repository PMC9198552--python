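"""Generator statistics, response-model geometry, and dataset round trips."""

import numpy as np
import pytest
from scipy import ndimage, stats

from iplorg import synth
from iplorg.phase import ENSEMBLE_SIGMA


# ---------------------------------------------------------------------------
# system configuration closed forms
# ---------------------------------------------------------------------------


def test_system_parameter_closed_forms():
    cfg = synth.SystemConfig()
    assert cfg.axial_resolution == pytest.approx(8.4e-6, abs=0.05e-6)
    assert round(cfg.full_duty_volume_rate) == 117
    assert cfg.volume_rate == pytest.approx(8.0)


def test_config_invariants_rejected():
    with pytest.raises(ValueError):
        synth.SystemConfig(lambda0=-1)
    with pytest.raises(ValueError):
        synth.SystemConfig(volume_period=0.001)  # faster than full duty
    with pytest.raises(ValueError):
        synth.SystemConfig(nz=4)


# ---------------------------------------------------------------------------
# speckle statistics
# ---------------------------------------------------------------------------


def test_zero_reflectivity_gives_zero_volume(small_config):
    phantom = synth.default_phantom(small_config)
    phantom.layer_reflectivities = [0.0] * len(phantom.layer_reflectivities)
    vol = synth.make_speckle_volume(phantom, small_config, seed=0)
    assert not vol.any()


def test_speckle_marginals_rayleigh_uniform(small_config):
    """Fully developed speckle: Rayleigh magnitudes, uniform phases."""
    phantom = synth.default_phantom(small_config)
    vol = synth.make_speckle_volume(phantom, small_config, seed=1)
    refl = phantom.reflectivity_volume(small_config)
    r = 0.62  # IPL plateau
    sel = np.abs(refl - r) < 1e-12
    sample = vol[sel][:100000]
    mags = np.abs(sample).astype(float)
    assert mags.mean() == pytest.approx(r * np.sqrt(np.pi) / 2, rel=0.01)
    ks = stats.kstest(mags, "rayleigh", args=(0, r / np.sqrt(2)))
    assert ks.pvalue > 0.01
    phases = np.angle(sample)
    hist, _ = np.histogram(phases, bins=36, range=(-np.pi, np.pi))
    chi2 = ((hist - hist.mean()) ** 2 / hist.mean()).sum()
    assert chi2 < stats.chi2.ppf(0.99, df=35)


def test_decorrelation_preserves_marginals_and_autocorrelation(small_config):
    """AR(1) evolution: lag-1 correlation exp(-dt/tau), Rayleigh marginals."""
    phantom = synth.default_phantom(small_config)
    tau = 0.5  # fast enough to measure within 30 volumes
    phantom.decorrelation_times = [tau] * len(phantom.decorrelation_times)
    base = synth.make_speckle_volume(phantom, small_config, seed=2)
    nt = 70
    series = np.broadcast_to(base, (nt,) + base.shape)
    series = synth.apply_decorrelation(series, phantom, small_config, seed=2)

    refl = phantom.reflectivity_volume(small_config)
    sel = np.abs(refl - 0.62) < 1e-12
    u = series[:, sel][:, :10000].astype(np.complex128)
    # sample lag-1 field correlation vs AR(1) theory
    num = (u[:-1] * np.conj(u[1:])).mean()
    den = (np.abs(u) ** 2).mean()
    rho_hat = (num / den).real
    rho = np.exp(-small_config.volume_period / tau)
    se = 3.0 / np.sqrt(u[:-1].size)
    assert abs(rho_hat - rho) < 3 * se + 0.01
    # marginal after 69 steps still Rayleigh
    mags = np.abs(u[-1])
    ks = stats.kstest(mags, "rayleigh", args=(0, 0.62 / np.sqrt(2)))
    assert ks.pvalue > 0.01


def test_infinite_tau_keeps_volumes_identical(static_dataset):
    phantom_free = static_dataset.volumes
    # ground truth is zero before stimulus onset, so the first volumes differ
    # only if decorrelation injected innovations
    assert np.array_equal(phantom_free[0], phantom_free[1])


# ---------------------------------------------------------------------------
# spatial response fields
# ---------------------------------------------------------------------------


def test_uniform_pattern_without_surround_is_constant(small_config):
    model = synth.ResponseModel()
    pattern = np.ones((small_config.ny, small_config.nx), dtype=np.uint8)
    field = synth.spatial_response_field(pattern, model, small_config.dx, edge_gain=1.0)
    assert np.allclose(field, 1.0, atol=1e-9)


def test_edge_ridge_calibrated_to_edge_gain(small_config):
    """Raw-field calibration: interior 1, ridge maximum = edge_gain."""
    model = synth.ResponseModel()
    pattern = synth.default_pattern(small_config)
    field = synth.spatial_response_field(
        pattern, model, small_config.dx, edge_gain=25.0 / 15.0
    )
    iy, ix = synth._interior_index(pattern)
    assert field[iy, ix] == pytest.approx(1.0)
    assert field.max() == pytest.approx(25.0 / 15.0, rel=1e-6)
    # far outside the pattern the field vanishes
    assert abs(field[0, 0]) < 1e-3


def test_edge_exceeds_interior_for_any_surround_weight():
    """1-D step-edge oracle: DoG response peaks at the edge when w_s > 0."""
    n = 400
    x = np.arange(n)
    step = (x >= n // 2).astype(float)
    sc, ss = 2.5, 5.0
    gc = ndimage.gaussian_filter1d(step, sc)
    gs = ndimage.gaussian_filter1d(step, ss)
    for ws in (0.2, 0.5, 0.8):
        dog = gc - ws * gs
        interior = dog[-1]
        assert dog.max() > interior


def test_pattern_validation_rejects_non_binary(small_config):
    model = synth.ResponseModel()
    bad = np.full((small_config.ny, small_config.nx), 0.5)
    with pytest.raises(ValueError):
        synth.spatial_response_field(bad, model, small_config.dx)


# ---------------------------------------------------------------------------
# temporal response
# ---------------------------------------------------------------------------


def test_temporal_response_zero_before_onset(small_config):
    t = small_config.times(30)
    protocol = synth.StimulusProtocol()
    model = synth.ResponseModel()
    courses = synth.temporal_response(t, protocol, model)
    for c in courses.values():
        assert np.all(c[: protocol.onset_volume] == 0.0)
        assert np.all(np.diff(c[protocol.onset_volume :]) >= 0)


def test_central_center_silent_under_continuous_stimulation(small_config):
    t = small_config.times(30)
    courses = synth.temporal_response(t, synth.StimulusProtocol(), synth.ResponseModel())
    assert np.all(courses["central_center"] == 0.0)


def test_central_center_full_amplitude_at_preferred_flicker(small_config):
    model = synth.ResponseModel()
    t = small_config.times(100)
    protocol = synth.StimulusProtocol(waveform="flicker", frequency=model.tcsf_peak)
    courses = synth.temporal_response(t, protocol, model)
    # B(peak) = 1, so the course approaches 1 at steady state
    assert courses["central_center"][-1] == pytest.approx(1.0, abs=0.01)


def test_temporal_bandpass_shape():
    model = synth.ResponseModel()
    assert synth.temporal_bandpass(0.0, model) == 0.0
    assert synth.temporal_bandpass(model.tcsf_peak, model) == pytest.approx(1.0)
    assert synth.temporal_bandpass(50.0, model) < 0.05
    grid = [1, 2, 3.3, 5, 6.7, 10, 12.5, 16.6, 25, 33, 55]
    b = np.array([synth.temporal_bandpass(f, model) for f in grid])
    peak = int(np.argmax(b))
    assert np.all(np.diff(b[: peak + 1]) >= 0) and np.all(np.diff(b[peak:]) <= 0)


def test_onset_after_record_rejected(small_config):
    t = small_config.times(3)
    with pytest.raises(ValueError):
        synth.temporal_response(t, synth.StimulusProtocol(onset_volume=4), synth.ResponseModel())


# ---------------------------------------------------------------------------
# OPL embedding
# ---------------------------------------------------------------------------


def test_embedding_zero_opl_is_identity(small_config):
    phantom = synth.default_phantom(small_config)
    vol = synth.make_speckle_volume(phantom, small_config, seed=3)
    series = vol[None].copy()
    truth = synth.GroundTruth(
        opl={k: np.zeros((1, small_config.ny, small_config.nx)) for k in ("inner", "central", "outer")},
        displacement=np.zeros(1),
        surface=phantom.ipl_lower_edge,
        pattern=synth.default_pattern(small_config),
    )
    out = synth.embed_opl_dynamics(series, truth, small_config)
    assert np.array_equal(out, series)


def test_embedding_phase_closed_form_and_linearity(small_config):
    """25 nm of OPL is 4*pi*25e-9/841e-9 ~ 0.3735 rad; embedding is linear."""
    phantom = synth.default_phantom(small_config)
    vol = np.ones((1, small_config.nz, small_config.ny, small_config.nx), np.complex64)
    shape = (1, small_config.ny, small_config.nx)

    def embed(dl):
        truth = synth.GroundTruth(
            opl={
                "inner": np.full(shape, dl),
                "central": np.zeros(shape),
                "outer": np.zeros(shape),
            },
            displacement=np.zeros(1),
            surface=phantom.ipl_lower_edge,
            pattern=synth.default_pattern(small_config),
        )
        out = synth.embed_opl_dynamics(vol, truth, small_config)
        iy, ix = 40, 48
        z_band = int(round(phantom.ipl_lower_edge[iy, ix])) - 7
        z_ref = int(round(phantom.ipl_lower_edge[iy, ix])) + 2
        return np.angle(out[0, z_band, iy, ix] * np.conj(out[0, z_ref, iy, ix]))

    phi1 = embed(25e-9)
    assert phi1 == pytest.approx(4 * np.pi * 25e-9 / 841e-9, rel=1e-4)
    assert embed(50e-9) == pytest.approx(2 * phi1, rel=1e-4)


def test_embedding_warns_on_wrap_hazard(small_config):
    phantom = synth.default_phantom(small_config)
    vol = np.ones((2, small_config.nz, small_config.ny, small_config.nx), np.complex64)
    shape = (2, small_config.ny, small_config.nx)
    big = np.zeros(shape)
    big[1] = 200e-9  # > lambda0 / 8 in one volume step
    truth = synth.GroundTruth(
        opl={"inner": big, "central": np.zeros(shape), "outer": np.zeros(shape)},
        displacement=np.zeros(2),
        surface=phantom.ipl_lower_edge,
        pattern=synth.default_pattern(small_config),
    )
    with pytest.warns(UserWarning, match="wrap"):
        synth.embed_opl_dynamics(vol, truth, small_config)


# ---------------------------------------------------------------------------
# bulk motion
# ---------------------------------------------------------------------------


def _zero_truth(config, phantom, nt):
    shape = (nt, config.ny, config.nx)
    return synth.GroundTruth(
        opl={k: np.zeros(shape) for k in ("inner", "central", "outer")},
        displacement=np.zeros(nt),
        surface=phantom.ipl_lower_edge,
        pattern=synth.default_pattern(config),
    )


def test_zero_amplitude_motion_is_identity(small_config):
    phantom = synth.default_phantom(small_config)
    vol = synth.make_speckle_volume(phantom, small_config, seed=4)[None]
    truth = _zero_truth(small_config, phantom, 1)
    params = synth.MotionParams(amplitude=0.0, drift=0.0)
    out = synth.apply_bulk_motion(vol.copy(), truth, small_config, params)
    assert np.allclose(out, vol, atol=1e-6)


def test_integer_voxel_shift_equals_roll(small_config, rng):
    vol = (rng.standard_normal((small_config.nz, 8, 8))
           + 1j * rng.standard_normal((small_config.nz, 8, 8)))
    from iplorg._util import axial_fourier_shift

    shifted = axial_fourier_shift(vol, 2.0)
    assert np.allclose(shifted, np.roll(vol, 2, axis=0), atol=1e-9)


def test_subvoxel_shift_matches_fourier_oracle(small_config, rng):
    """Half-voxel shift agrees with an independent FFT-theorem evaluation."""
    from iplorg._util import axial_fourier_shift

    nz = small_config.nz
    vol = (rng.standard_normal((nz, 4, 4)) + 1j * rng.standard_normal((nz, 4, 4)))
    shifted = axial_fourier_shift(vol, 0.5)
    k = np.fft.fftfreq(nz)
    oracle = np.fft.ifft(
        np.fft.fft(vol, axis=0) * np.exp(-2j * np.pi * k * 0.5)[:, None, None], axis=0
    )
    assert np.max(np.abs(shifted - oracle)) / np.max(np.abs(oracle)) < 1e-10


def test_motion_exceeding_quarter_depth_rejected(small_config):
    phantom = synth.default_phantom(small_config)
    vol = np.ones((2, small_config.nz, small_config.ny, small_config.nx), np.complex64)
    truth = _zero_truth(small_config, phantom, 2)
    params = synth.MotionParams(amplitude=small_config.nz / 2, drift=0.0)
    with pytest.raises(ValueError):
        synth.apply_bulk_motion(vol, truth, small_config, params)


# ---------------------------------------------------------------------------
# dataset composition and serialisation
# ---------------------------------------------------------------------------


def test_same_seed_reproduces_identical_arrays(small_config):
    a = synth.generate_dataset(config=small_config, seed=42, n_volumes=6)
    b = synth.generate_dataset(config=small_config, seed=42, n_volumes=6)
    assert np.array_equal(a.volumes, b.volumes)
    for k in a.truth.opl:
        assert np.array_equal(a.truth.opl[k], b.truth.opl[k])


def test_default_protocol_timing(small_dataset):
    """Baseline volumes precede onset; truth is zero during baseline."""
    assert small_dataset.protocol.onset_volume == 4
    for k, arr in small_dataset.truth.opl.items():
        assert np.all(arr[:4] == 0.0)


def test_truth_amplitude_by_construction(small_config):
    """The smoothed truth readout reproduces the model amplitudes exactly."""
    model = synth.ResponseModel()
    truth = synth.build_truth(
        small_config, synth.StimulusProtocol(), model,
        synth.default_phantom(small_config), 70, background=None,
    )
    masks = synth.analysis_mask_geometry(truth.pattern, model, small_config)
    t = small_config.times(70)
    rise = synth.temporal_response(t, synth.StimulusProtocol(), model)["inner"][-1]
    sm = ndimage.gaussian_filter(truth.opl["inner"][-1], ENSEMBLE_SIGMA, mode="wrap")
    assert sm[masks["center"]].mean() == pytest.approx(model.amp_inner * rise, rel=1e-6)
    assert sm[masks["edge"]].mean() == pytest.approx(
        model.amp_inner * model.edge_gain * rise, rel=1e-6
    )


def test_flicker_halves_photon_dose():
    cont = synth.StimulusProtocol()
    flick = synth.StimulusProtocol(waveform="flicker", frequency=12.5)
    assert flick.photon_dose_factor == 0.5 * cont.photon_dose_factor


def test_save_load_round_trip(tmp_path, small_config):
    ds = synth.generate_dataset(config=small_config, seed=9, n_volumes=6)
    path = tmp_path / "data.h5"
    synth.save_dataset(ds, path)
    back = synth.load_dataset(path)
    assert np.array_equal(back.volumes, ds.volumes)
    for k in ds.truth.opl:
        assert np.array_equal(back.truth.opl[k], ds.truth.opl[k])
    assert np.array_equal(back.truth.surface, ds.truth.surface)
    assert back.config == ds.config
    assert back.protocol.waveform == ds.protocol.waveform
    assert (tmp_path / "data.h5.json").exists()


def test_phantom_invariants():
    cfg = synth.SystemConfig(nx=16, ny=16, nz=48)
    phantom = synth.default_phantom(cfg)
    with pytest.raises(ValueError):
        synth.RetinaPhantom(
            phantom.layer_boundaries[::-1],
            phantom.layer_reflectivities,
            phantom.decorrelation_times,
            phantom.ipl_lower_edge,
        )
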