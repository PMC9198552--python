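# iplorg — phase-sensitive OCT optoretinography of IPL sub-layers

Neurons of the inner retina — bipolar, amacrine and ganglion cells — make
their synaptic connections in distinct depth strata of the inner plexiform
layer (IPL). When the retina is stimulated with light, these strata swell or
shrink by nanometres, changing the optical path length (OPL) between an IPL
sub-layer and the tissue beneath it. Phase-sensitive full-field swept-source
OCT (FF-SS-OCT) can resolve these changes interferometrically: an OPL change
`dl` appears as a phase change `phi = 4*pi*dl / lambda0` (~67 nm per radian
at 841 nm), letting functional contributions of different retinal cell
classes (ON vs. OFF pathways, sustained vs. transient cells) be separated by
depth without resolving single cells.

`iplorg` is a tested, reusable implementation of that analysis for
researchers working on functional OCT / optoretinography:

* **`iplorg.synth`** — a seeded synthetic FF-SS-OCT generator (layered
  speckle phantom, per-layer temporal decorrelation, bulk pulsatile motion,
  and stimulus-evoked per-sub-layer OPL dynamics with centre-surround edge
  enhancement and flicker tuning) with full ground truth;
* **`iplorg.register`** — blockwise correlation registration of complex
  volume series with subvoxel axial refinement;
* **`iplorg.segment`** — IPL lower-edge segmentation via axial-gradient
  point selection, diffusion-map embedding, DBSCAN, surface fitting and
  volume flattening;
* **`iplorg.phase`** — temporal cross-spectra `dU(t,dt) = U(t) conj(U(t+dt))`,
  two-voxel depth-band pairing, circular Gaussian ensemble averaging
  (sigma = 4 px), and an extended Knox-Thompson solver that finds, per pixel,
  the phase time course consistent with all cross-spectrum lags;
* **`iplorg.response`** — background-corrected time courses, edge/centre
  steady-state amplitudes (mean over the last 625 ms), lateral profiles and
  the flicker frequency-response curve;
* **`iplorg.photometry`** — retinal irradiance → illuminance → luminance
  conversions with the bundled CIE 1924 photopic efficiency function.

See `docs/methods.md` for the model, parameter defaults and limitations.

## Worked example

Generate a desk-scale measurement sequence (160×128×64 voxels × 70 volumes
at 8 Hz, continuous stimulation with a centred square pattern) and run the
full analysis:

```python
import iplorg

ds = iplorg.generate_dataset(seed=0)          # ~30 s
res = iplorg.run_pipeline(ds)                 # ~30 s
for band in ("inner", "central", "outer"):
    s = res.steady[band]
    print(f"{band:8s} centre {s['center']*1e9:+6.2f} nm   "
          f"edge {s['edge']*1e9:+6.2f} nm")
```

```
inner    centre +14.62 nm   edge +25.56 nm
central  centre  +1.50 nm   edge  +9.49 nm
outer    centre  -9.38 nm   edge  -7.39 nm
```

Reading the numbers: the inner sub-layer (ON-pathway synapses, closest to
the ganglion cells) swells by ~15 nm across the stimulated square and by
~25 nm at its edges — the centre-surround receptive fields make retinal
responses edge-sensitive. The central sub-layer responds only at the pattern
edges (~10 nm) under continuous stimulation; its centre response is at the
noise floor. The outer sub-layer (OFF pathway) *shrinks*. Under 12.5 Hz
flicker (`iplorg.StimulusProtocol(waveform="flicker", frequency=12.5)`) the
central sub-layer — where transient cells stratify — additionally gains a
~15 nm full-field response:

```python
ds_f = iplorg.generate_dataset(
    protocol=iplorg.StimulusProtocol(waveform="flicker", frequency=12.5),
    seed=0,
)
res_f = iplorg.run_pipeline(ds_f)
print(f"central centre {res_f.steady['central']['center']*1e9:+6.2f} nm")
```

```
central centre +16.11 nm
```

The same steps are available from the shell (`iplorg generate`, `iplorg
register`, `iplorg segment`, `iplorg phase`, `iplorg response`, or `iplorg
pipeline` in one go; `iplorg photometry` converts stimulation levels), with
HDF5 containers between stages and CSV/JSON/TIFF outputs.

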