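# pwus — plane-wave ultrasound toolkit

`pwus` is a software counterpart to a portable plane-wave ultrasound
system for automated bladder monitoring. Such a device transmits
unfocused, tilted plane waves from a small phased array (here: 32
elements, 500 µm pitch, 3 MHz), streams the raw per-element RF records
("pre-beamformed channel data") to a host, and performs all image
formation in software. This package reproduces that processing chain on
synthetic data, end to end and without hardware:

* **`pwus.fieldsim`** — point-source acoustic field synthesis (beam
  steering, grating-lobe inspection) and simulation of multi-angle RF
  channel data from point-scatterer fields;
* **`pwus.beamform`** — delay-and-sum (DAS) plane-wave compounding on a
  Cartesian grid, with coherence-factor (COH) and aperture-statistics
  (STD) pixel weighting, envelope detection, log compression and fan
  masking;
* **`pwus.metrics`** — image-quality metrics: lateral PSF FWHM,
  depth-dependent SNR(z) = 20·log₁₀(µ_z/σ_z) over repeated acquisitions,
  contrast ratio CR = 20·log₁₀(µ_lesion/µ_bck) and contrast-to-noise
  ratio CNR = (µ_bck − µ_lesion)/√(σ²_bck ± σ²_lesion);
* **`pwus.phantoms`** — wire-target resolution phantoms, speckle/lesion
  contrast phantoms, and fan-masked synthetic bladder B-mode scenes with
  ground-truth masks (partially visible bladder, small central bladder,
  confounding dark regions);
* **`pwus.segmentation`** — a minimal 2-class U-Net (5 blocks, 6 first
  channels doubling to 96 at the bottleneck, 528×352 single-channel
  input) written in pure NumPy, with the fan-aware 20-fold augmentation
  and a deterministic classical threshold baseline;
* **`pwus.segeval`** — pixel-counting evaluation: missing/false bladder
  fractions relative to the ground-truth area, IoU, cohort summaries;
* **`pwus.io`** — a self-describing HDF5 frame container that stores
  payloads together with the metadata needed to re-run reconstruction.

The beamforming model: a plane wave steered by angle θ reaches the pixel
(x, z) after path z·cosθ + x·sinθ; the echo returns to element e over
√((x−x_e)² + z²). DAS sums, for every pixel, the linearly interpolated
channel samples at this round-trip delay over the aperture, per angle;
coherent compounding averages the per-angle RF images before envelope
detection.

## Worked example

```
$ python examples/02_wire_resolution.py
wire at  10.0 mm, DAS: lateral FWHM =   432.8 um
wire at  10.0 mm, STD: lateral FWHM =   326.5 um
wire at 100.0 mm, DAS: lateral FWHM =  1035.6 um
wire at 100.0 mm, STD: lateral FWHM =   901.5 um
```

A wire target is simulated at each depth (21 plane waves over ±16°,
40 MSa/s), beamformed on a fine grid, compounded, envelope-detected,
and the lateral full width at half maximum of the point spread function
is measured. Resolution worsens with depth as the 16 mm aperture
subtends a smaller angle, and STD weighting narrows the mainlobe
relative to plain DAS.

```
$ python examples/05_train_unet.py
trained 15 epochs, loss 0.222 -> 0.014
held-out median IoU:        0.925
median missing fraction:    0.011
median false fraction:      0.070
```

Here the U-Net is trained at desk scale (200 synthetic central-scenario
scenes at 64×96 px) and evaluated on 20 held-out scenes by pixel
counting: the fractions state how much of the true bladder area was
missed or falsely added, and IoU is the intersection over union of
predicted and true masks.

The other examples demonstrate field synthesis and grating lobes
(`01`), lesion contrast versus compounding angle count (`03`) and the
classical baseline across the three bladder scenarios (`04`). A thin
CLI (`pwus phantom|simulate|beamform|bmode|metrics|train-seg|segment|eval-seg|report`)
wraps the same functions for shell use.

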