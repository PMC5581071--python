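"""Reference values for the digital mouse phantom.

Whole-organ ¹⁸F-FDG uptake levels (%ID/g at the 45–60 min window) at the
scale reported for subcutaneous NSCLC xenograft mice quantified by ex vivo
γ-counting, used as the simulator's default ground truth, together with
between-animal spreads for cohort sampling, typical wet organ weights, and
reference one-tissue-compartment parameter pairs for the tumor.
"""

from __future__ import annotations

__all__ = [
    "UPTAKE_PIDG_MEAN",
    "UPTAKE_PIDG_SD",
    "ORGAN_WET_WEIGHT_G",
    "TUMOR_1TCM_HIGHRES",
    "TUMOR_1TCM_LOWRES",
    "PSF_PRESETS",
]

#: Mean γ-counter uptake (%ID/g) per organ: default simulation truth.
UPTAKE_PIDG_MEAN: dict[str, float] = {
    "brain": 6.54,
    "heart": 22.01,
    "liver": 1.97,
    "kidney": 5.18,
    "tumor": 3.53,
    "muscle": 1.06,
}

#: Between-animal SD of the same quantities, for stochastic cohorts.
UPTAKE_PIDG_SD: dict[str, float] = {
    "brain": 2.73,
    "heart": 9.64,
    "liver": 0.54,
    "kidney": 1.55,
    "tumor": 1.02,
    "muscle": 0.45,
}

#: Typical wet weights (g) for a ~20 g mouse, used by the γ-counting simulator.
ORGAN_WET_WEIGHT_G: dict[str, float] = {
    "brain": 0.40,
    "heart": 0.15,
    "liver": 1.10,
    "kidney": 0.20,
    "tumor": 0.20,
    "muscle": 0.30,
}

#: Tumor one-tissue-compartment (K1 mL/min/g, k2 min⁻¹) reference pairs:
#: high-resolution (PSF-modelled) and low-resolution reconstructions.
TUMOR_1TCM_HIGHRES: tuple[float, float] = (0.23, 0.0044)
TUMOR_1TCM_LOWRES: tuple[float, float] = (0.08, 0.0023)

#: Effective reconstructed resolution presets (Gaussian FWHM, mm).
#: ``clinical`` is a whole-body scanner without resolution recovery,
#: ``clinical_psf`` the same scanner with PSF-based iterative recovery
#: (effective width is a stand-in; vendors do not publish it), and
#: ``micropet`` a dedicated small-animal scanner.
PSF_PRESETS: dict[str, float] = {
    "ideal": 0.0,
    "micropet": 1.66,
    "clinical_psf": 2.0,
    "clinical": 3.3,
}
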