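"""Digital-mouse acquisition simulator.

Renders calibration-phantom, static and dynamic PET acquisitions of a
voxelised organ phantom with known ground truth.  The scanner model is
deliberately simple and fully transparent:

* organ activity is the analytic mean of the organ's (possibly decaying)
  time course over each frame, so noise-free unblurred voxels match the
  model exactly;
* reconstruction resolution is an isotropic Gaussian point-spread
  function (FWHM in mm) applied per frame;
* count noise is zero-mean Gaussian with SD ∝ √activity/√(frame
  duration), a tractable surrogate for Poisson counting (a Poisson mode
  is available);
* physical decay uses the ¹⁸F constants of :mod:`petquant.dosimetry`.

All randomness flows from one root seed through named substreams, so each
stage is independently reproducible bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .blood import BloodInputModel
from .dosimetry import DECAY_LOG2, F18_HALF_LIFE_MIN, ConversionFactor, DoseRecord, conversion_factor
from .image import DynamicImage
from .kinetics import OneTissueParams, _frame_average
from .phantom import DEFAULT_GRID_SHAPE, Phantom
from .quantify import BiodistSample
from .reference import ORGAN_WET_WEIGHT_G
from .schedule import FrameSchedule

__all__ = [
    "KBQ_PER_UCI",
    "BQ_PER_UCI",
    "IDEAL_CF",
    "AcquisitionConfig",
    "GroundTruth",
    "simulate_dynamic_scan",
    "simulate_calibration_phantom",
    "simulate_biodistribution",
]

KBQ_PER_UCI = 37.0
BQ_PER_UCI = 37_000.0

#: Conversion factor of an ideally calibrated scanner that reads true
#: concentration: (μCi/g)/(kBq/ml) is then pure unit conversion, 1/37.
IDEAL_CF = 1.0 / KBQ_PER_UCI

_STREAMS = {"noise": 1, "calibration": 2, "biodist": 3, "cohort": 4}


def _substream(seed: int, name: str) -> np.random.Generator:
    return np.random.default_rng([int(seed), _STREAMS[name]])


@dataclass(frozen=True)
class AcquisitionConfig:
    """Scanner and acquisition settings for the simulator.

    ``psf_fwhm`` is the effective reconstructed resolution in mm (see
    :data:`petquant.reference.PSF_PRESETS`); ``noise_scale`` sets the
    Gaussian noise SD at 1 kBq/ml and 1 min frame duration, in kBq/ml.
    ``apply_decay`` renders physically decaying activity (reference time
    is injection, t = 0 of the schedule); when off, images are
    decay-corrected, as reconstructed clinical images are.
    """

    voxel_size: float = 1.0
    shape: tuple[int, int, int] = DEFAULT_GRID_SHAPE
    psf_fwhm: float = 0.0
    noise_scale: float = 0.0
    noise_mode: str = "gaussian"
    schedule: FrameSchedule = field(default_factory=FrameSchedule.static)
    apply_decay: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.psf_fwhm < 0 or self.noise_scale < 0 or self.voxel_size <= 0:
            raise ValueError("psf_fwhm, noise_scale must be >= 0 and voxel_size > 0")
        if self.noise_mode not in ("gaussian", "poisson"):
            raise ValueError("noise_mode must be 'gaussian' or 'poisson'")


@dataclass(frozen=True)
class GroundTruth:
    """Everything the simulator knew, echoed verbatim for recovery tests."""

    uptake: dict[str, float]  # static organs, %ID/g
    suv: dict[str, float]  # implied SUV (mean = max for uniform organs)
    kinetic: dict[str, OneTissueParams]
    blood_fraction: dict[str, float]
    concentration: dict[str, float]  # static decay-corrected kBq/ml
    frame_means: dict[str, np.ndarray]  # analytic noise-free voxel values
    dose: DoseRecord
    blood: BloodInputModel
    schedule: FrameSchedule


def _decay_lambda() -> float:
    return DECAY_LOG2 / F18_HALF_LIFE_MIN


def _organ_frame_means(
    organ, concentration: float, blood: BloodInputModel, sched: FrameSchedule, apply_decay: bool
) -> np.ndarray:
    """Analytic frame-mean activity (kBq/ml) for one organ."""
    lam = _decay_lambda() if apply_decay else 0.0

    if not organ.is_kinetic:
        if lam == 0.0:
            return np.full(sched.n_frames, concentration)
        t0, t1 = sched.start, sched.end
        mean_decay = (np.exp(-lam * t0) - np.exp(-lam * t1)) / (lam * sched.duration)
        return concentration * mean_decay

    k = organ.kinetic or OneTissueParams(0.0, 0.0)
    bf = organ.blood_fraction

    def curve(t):
        c = (1.0 - bf) * blood.tissue_curve(k.K1, k.k2, t) if k.K1 > 0 else 0.0
        if bf > 0:
            c = c + bf * blood(t)
        if lam > 0:
            c = c * np.exp(-lam * np.asarray(t))
        return np.asarray(c) if np.ndim(c) else np.full(np.shape(t), float(c))

    return _frame_average(curve, sched.start, sched.duration)


def simulate_dynamic_scan(
    phantom: Phantom,
    config: AcquisitionConfig,
    dose: DoseRecord,
    blood: BloodInputModel | None = None,
) -> tuple[DynamicImage, GroundTruth]:
    """Render an acquisition of the phantom and echo its ground truth.

    Static organs (``uptake`` in %ID/g) are painted at the decay-corrected
    concentration that makes the calibrated quantification exact:
    L = uptake · density · I / (100 · CF_ideal) with I the scan dose from
    ``dose``.  Kinetic organs follow the one-tissue model driven by
    ``blood``; the per-organ analytic frame means are returned in the
    ground truth as the oracle for TAC extraction.
    """
    if phantom.voxel_size != config.voxel_size or phantom.shape != tuple(config.shape):
        raise ValueError("phantom grid does not match the acquisition config")
    blood = blood or BloodInputModel()
    sched = config.schedule
    scan_dose_uci = dose.scan_dose()

    uptake, suv, kinetic, blood_fraction, conc, frame_means = {}, {}, {}, {}, {}, {}
    volume = np.zeros(phantom.shape + (sched.n_frames,), dtype=float)
    for organ in phantom.organs:
        if organ.is_kinetic:
            kinetic[organ.name] = organ.kinetic or OneTissueParams(0.0, 0.0)
            blood_fraction[organ.name] = organ.blood_fraction
            c = 0.0
        else:
            uptake[organ.name] = organ.uptake
            suv[organ.name] = organ.uptake * organ.density * dose.weight / 100.0
            c = organ.uptake * organ.density * scan_dose_uci / (100.0 * IDEAL_CF)
            conc[organ.name] = c
        fm = _organ_frame_means(organ, c, blood, sched, config.apply_decay)
        frame_means[organ.name] = fm
        volume[phantom.masks[organ.name]] = fm

    if config.psf_fwhm > 0:
        sigma = config.psf_fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / config.voxel_size
        for i in range(sched.n_frames):
            volume[..., i] = ndimage.gaussian_filter(volume[..., i], sigma, mode="constant")

    if config.noise_scale > 0:
        rng = _substream(config.seed, "noise")
        dur = sched.duration[np.newaxis, np.newaxis, np.newaxis, :]
        if config.noise_mode == "gaussian":
            sd = config.noise_scale * np.sqrt(np.clip(volume, 0.0, None)) / np.sqrt(dur)
            volume = volume + rng.normal(0.0, 1.0, volume.shape) * sd
        else:  # counts per voxel ~ Poisson(activity·duration/scale)
            lam = np.clip(volume, 0.0, None) * dur / config.noise_scale
            volume = rng.poisson(lam) * config.noise_scale / dur

    img = DynamicImage(
        data=volume,
        voxel_size=config.voxel_size,
        schedule=sched,
        decay_corrected=not config.apply_decay,
    )
    truth = GroundTruth(
        uptake=uptake,
        suv=suv,
        kinetic=kinetic,
        blood_fraction=blood_fraction,
        concentration=conc,
        frame_means=frame_means,
        dose=dose,
        blood=blood,
        schedule=sched,
    )
    return img, truth


def simulate_calibration_phantom(
    b1_uci: float,
    b2_g: float,
    config: AcquisitionConfig,
    frame_duration_min: float = 5.0,
) -> tuple[DynamicImage, ConversionFactor]:
    """Scan a uniform phantom of B1 μCi diluted in B2 g of water.

    The ideal reading is B1/B2·37 kBq/ml; noise (if configured) perturbs
    the image, and B3 is measured as the mean over the central half of the
    volume.  Returns the image and the resulting conversion factor record.
    """
    if b1_uci <= 0 or b2_g <= 0:
        raise ValueError("phantom dose and weight must be positive")
    ideal = b1_uci / b2_g * KBQ_PER_UCI
    vol = np.full(tuple(config.shape), ideal, dtype=float)
    if config.noise_scale > 0:
        rng = _substream(config.seed, "calibration")
        if config.noise_mode == "gaussian":
            sd = config.noise_scale * np.sqrt(ideal) / np.sqrt(frame_duration_min)
            vol = vol + rng.normal(0.0, sd, vol.shape)
        else:
            lam = ideal * frame_duration_min / config.noise_scale
            vol = rng.poisson(lam, vol.shape) * config.noise_scale / frame_duration_min
    center = tuple(slice(n // 4, n - n // 4) for n in vol.shape)
    b3 = float(vol[center].mean())
    img = DynamicImage(
        data=vol,
        voxel_size=config.voxel_size,
        schedule=FrameSchedule.single(0.0, frame_duration_min),
    )
    return img, conversion_factor(b1_uci, b2_g, b3)


def simulate_biodistribution(
    uptake: dict[str, float],
    dose: DoseRecord,
    noise_cv: float = 0.0,
    seed: int = 0,
    wet_weights: dict[str, float] | None = None,
    count_time=None,
) -> list[BiodistSample]:
    """γ-counter measurements consistent with the given true uptake.

    Noise-free counts invert the %ID/g definition exactly:
    counts = uptake/100 · weight · I(count_time) · 37000 Bq.  ``noise_cv``
    applies multiplicative Gaussian measurement noise with that
    coefficient of variation (clipped at zero counts).
    """
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    wet_weights = dict(ORGAN_WET_WEIGHT_G if wet_weights is None else wet_weights)
    count_time = dose.scan_time if count_time is None else count_time
    from .dosimetry import ClockTime, injected_dose, scan_dose

    count_time = ClockTime.parse(count_time)
    dose_at_count = scan_dose(injected_dose(dose), dose.injection_time, count_time)
    rng = _substream(seed, "biodist")
    samples = []
    for organ, pidg in uptake.items():
        w = wet_weights[organ]
        counts = pidg / 100.0 * w * dose_at_count * BQ_PER_UCI
        if noise_cv > 0:
            counts = max(0.0, counts * (1.0 + noise_cv * rng.standard_normal()))
        samples.append(
            BiodistSample(organ=organ, wet_weight=w, counts=counts, count_time=count_time)
        )
    return samples
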