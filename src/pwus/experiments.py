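"""End-to-end study recipes combining the simulator, beamformer and metrics.

These functions reproduce, at desk scale, the characterization studies a
plane-wave system is benched with: wire-target PSF/FWHM measurement,
lesion-phantom contrast versus compounding angle count, and synthetic
bladder segmentation training/evaluation.
"""

from __future__ import annotations

import numpy as np

from .beamform import ReconGrid, bmode_pipeline, compound, das_beamform, envelope, weighted_beamform
from .fieldsim import ArrayGeometry, PlaneWaveSequence, simulate_channel_data
from .metrics import PSFMeasurement, ROIStats, contrast_ratio, psf_lateral_fwhm, roi_stats
from .phantoms import lesion_phantom, make_bladder_dataset, wire_phantom
from .segeval import seg_fractions, summarize
from .segmentation import UNetConfig, classical_segment, segment, train_unet

__all__ = [
    "simulate_wire",
    "wire_psf_fwhm",
    "lesion_contrast_vs_angles",
    "bladder_segmentation_study",
]


def simulate_wire(
    depth_mm: float,
    n_angles: int = 21,
    span_deg: float = 16.0,
    geometry: ArrayGeometry | None = None,
    sampling_rate: float = 40e6,
    lateral_mm: float = 0.0,
):
    """Noise-free channel data for a single wire target at the given depth."""
    geometry = geometry or ArrayGeometry()
    seq = PlaneWaveSequence.from_span(n_angles, span_deg, tx_frequency=geometry.center_frequency)
    scat = wire_phantom([depth_mm], lateral_mm)
    return simulate_channel_data(scat, geometry, seq, sampling_rate=sampling_rate)


def wire_psf_fwhm(
    depth_mm: float,
    n_angles: int = 21,
    span_deg: float = 16.0,
    method: str = "das",
    dx_mm: float = 0.025,
    data=None,
) -> PSFMeasurement:
    """Lateral FWHM of the point spread function of a simulated wire target.

    Simulates (unless ``data`` is supplied), beamforms a fine local grid
    around the wire (25 um default lateral spacing), compounds
    coherently, envelope-detects and measures the lateral width through
    the peak. The lateral window scales with depth so the full mainlobe
    is always captured.
    """
    if data is None:
        data = simulate_wire(depth_mm, n_angles, span_deg)
    half_x = max(2.5, 0.05 * depth_mm)
    grid = ReconGrid(
        -half_x, half_x, int(round(2 * half_x / dx_mm)) + 1,
        depth_mm - 1.5, depth_mm + 1.5, 61,
    )
    if method == "das":
        bfi = das_beamform(data, grid)
    else:
        bfi = weighted_beamform(data, grid, method)
    env = envelope(compound(bfi))
    return psf_lateral_fwhm(env, grid, (0.0, depth_mm), method=method, n_angles=n_angles)


def lesion_contrast_vs_angles(
    angle_counts=(1, 5, 11, 21),
    lesion_depth_mm: float = 25.0,
    lesion_radius_mm: float = 3.0,
    density_per_mm2: float = 4.0,
    seed: int = 0,
) -> dict:
    """Contrast ratio of an anechoic lesion versus compounding angle count.

    One 21-angle acquisition is simulated; angle subsets (centred,
    symmetric) are compounded from the same channel data, and CR is
    computed from circular lesion/background ROIs at the lesion depth on
    the linear envelope.
    """
    geometry = ArrayGeometry()
    region = (-9.0, 9.0, lesion_depth_mm - 7.0, lesion_depth_mm + 7.0)
    scat = lesion_phantom(region, density_per_mm2, (0.0, lesion_depth_mm),
                          lesion_radius_mm, amplitude_ratio=0.0, seed=seed)
    seq = PlaneWaveSequence.from_span(21, 16.0)
    data = simulate_channel_data(scat, geometry, seq)
    grid = ReconGrid(-8.0, 8.0, 161, lesion_depth_mm - 6.0, lesion_depth_mm + 6.0, 121)
    bfi = das_beamform(data, grid)
    out = {}
    for n in angle_counts:
        # centred symmetric subset of the 21 transmitted angles
        idx = np.round(np.linspace(0, 20, n)).astype(int) if n > 1 else np.array([10])
        env = envelope(bfi.images[idx].mean(axis=0))
        lesion = roi_stats(env, grid, (0.0, lesion_depth_mm), lesion_radius_mm * 0.7,
                           role="lesion")
        bck = roi_stats(env, grid, (5.5, lesion_depth_mm), lesion_radius_mm * 0.7,
                        role="background")
        out[n] = contrast_ratio(lesion, bck)
    return out


def bladder_segmentation_study(
    n_train: int = 200,
    n_eval: int = 20,
    shape: tuple = (64, 96),
    scenario: str = "central",
    epochs: int = 15,
    depth: int = 3,
    first_channels: int = 6,
    learning_rate: float = 1e-3,
    seed: int = 0,
) -> dict:
    """Train the NumPy U-Net on synthetic bladder scenes and evaluate it.

    Generates ``n_train`` training and ``n_eval`` held-out scenes of one
    scenario at a reduced raster size, trains the network, segments the
    held-out scenes and returns the per-image fractions/IoU plus cohort
    summary. Also reports predicted/true mask areas for the
    area-recovery check.
    """
    train = make_bladder_dataset(n_train, scenario=scenario, shape=shape, seed=seed)
    evalset = make_bladder_dataset(n_eval, scenario=scenario, shape=shape, seed=seed + 10_000)
    config = UNetConfig(
        depth=depth,
        first_channels=first_channels,
        input_hw=shape,
        batch_size=4,
        learning_rate=learning_rate,
        max_epochs=epochs,
        seed=seed,
    )
    pairs = [(li.image.astype(np.float32) / 255.0, li.mask) for li in train]
    model = train_unet(pairs, config)
    results, pred_areas, true_areas = [], [], []
    for li in evalset:
        pred = segment(model, li.image.astype(np.float32) / 255.0)
        results.append(seg_fractions(pred, li.mask, fan=li.fan))
        pred_areas.append(int((pred.astype(bool) & li.fan).sum()))
        true_areas.append(int(li.mask.sum()))
    return {
        "model": model,
        "results": results,
        "summary": summarize(results),
        "pred_areas": pred_areas,
        "true_areas": true_areas,
    }
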