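"""Scalar PET quantification: ROI statistics, %ID/g, SUV, SNR, T/NT and
γ-counter biodistribution conversion.

The central quantity is percent injected dose per gram,

    %ID/g = (CF · L / I) · 100,

with L the ROI mean reading (kBq/ml), I the dose on board at scan time
(μCi) and CF the phantom conversion factor.  SUV normalises by dose per
gram of body weight instead: SUV = TA / (IA / W) with TA in μCi/ml.
SUV_max uses the hottest ROI voxel, %ID/g the ROI mean, mirroring how the
two are used in practice.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dosimetry import ClockTime, ConversionFactor, DoseRecord, injected_dose, scan_dose

__all__ = [
    "ROIStats",
    "BiodistSample",
    "roi_stats",
    "percent_id_per_g",
    "suv",
    "suv_max",
    "snr",
    "tnt_ratio",
    "biodist_percent_id_per_g",
    "quant_table",
]

KBQ_PER_UCI = 37.0
BQ_PER_UCI = 37_000.0


@dataclass(frozen=True)
class ROIStats:
    """Mean (Av), max and sample SD of voxel activity within an ROI (kBq/ml)."""

    mean: float
    max: float
    sd: float
    n_voxels: int

    def __post_init__(self) -> None:
        if self.n_voxels < 1:
            raise ValueError("ROI must contain at least one voxel")
        if self.max < self.mean or self.sd < 0:
            raise ValueError("inconsistent ROI statistics")


@dataclass(frozen=True)
class BiodistSample:
    """One γ-counter measurement: organ, wet weight (g), counts (Bq)."""

    organ: str
    wet_weight: float
    counts: float
    count_time: ClockTime

    def __post_init__(self) -> None:
        object.__setattr__(self, "count_time", ClockTime.parse(self.count_time))
        if self.wet_weight <= 0:
            raise ValueError("wet weight must be positive")
        if self.counts < 0:
            raise ValueError("counts must be >= 0")


def roi_stats(frame: np.ndarray, mask: np.ndarray) -> ROIStats:
    """Mean/max/sample-SD over masked voxels of one frame.

    SD uses the n−1 denominator (0 for a single voxel).
    """
    frame = np.asarray(frame, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != frame.shape:
        raise ValueError(f"mask shape {mask.shape} does not match frame {frame.shape}")
    vals = frame[mask]
    if vals.size == 0:
        raise ValueError("empty ROI mask")
    sd = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
    return ROIStats(mean=float(vals.mean()), max=float(vals.max()), sd=sd, n_voxels=vals.size)


def percent_id_per_g(roi_mean_kbq_ml: float, scan_dose_uci: float, cf) -> float:
    """%ID/g = (CF · L / I) · 100."""
    if scan_dose_uci <= 0:
        raise ValueError("scan dose must be positive")
    return float(cf) * roi_mean_kbq_ml / scan_dose_uci * 100.0


def suv(tissue_activity_uci_ml: float, injected_uci: float, weight_g: float) -> float:
    """SUV = TA / (IA / W); unitless (strictly g/ml)."""
    if injected_uci <= 0 or weight_g <= 0:
        raise ValueError("injected activity and weight must be positive")
    return tissue_activity_uci_ml / (injected_uci / weight_g)


def suv_max(stats: ROIStats, injected_uci: float, weight_g: float) -> float:
    """SUV of the hottest ROI voxel; converts the max reading from kBq/ml."""
    return suv(stats.max / KBQ_PER_UCI, injected_uci, weight_g)


def snr(stats: ROIStats) -> float:
    """Signal-to-noise ratio of a region, Av/SD."""
    if stats.sd == 0:
        raise ValueError("SNR undefined for a constant region (SD = 0)")
    return stats.mean / stats.sd


def tnt_ratio(tumor_value: float, muscle_value: float) -> float:
    """Tumor-to-normal-tissue ratio, muscle taken as normal tissue.

    Cohort-level T/NT should be the mean of per-animal ratios, not the
    ratio of cohort means — the two differ whenever uptake varies across
    animals.
    """
    if muscle_value <= 0:
        raise ValueError("muscle value must be positive")
    return tumor_value / muscle_value


def biodist_percent_id_per_g(
    sample: BiodistSample, rec: DoseRecord, *, exact_ln2: bool = False
) -> float:
    """Convert γ-counter Bq into %ID/g.

    The injected dose is decay-corrected to the counting time, so the
    result is independent of when the sample was counted.
    """
    g = injected_dose(rec, exact_ln2=exact_ln2)
    dose_at_count = scan_dose(g, rec.injection_time, sample.count_time, exact_ln2=exact_ln2)
    activity_uci = sample.counts / BQ_PER_UCI
    return 100.0 * (activity_uci / sample.wet_weight) / dose_at_count


def quant_table(
    images,
    masks,
    doses,
    cf: ConversionFactor,
    sources=None,
    animal_ids=None,
) -> pd.DataFrame:
    """Quantify a cohort of static scans into a tidy organ × source table.

    Parameters
    ----------
    images : sequence of 3-D arrays (kBq/ml)
        One static frame per scan.
    masks : sequence of dict[str, bool array]
        Organ masks per scan; organ sets must agree across scans.
    doses : sequence of DoseRecord
    cf : ConversionFactor
    sources, animal_ids : optional sequences of labels per scan

    Returns
    -------
    DataFrame with columns animal, source, organ, pid_g, suv_max, snr
    (snr is NaN for constant regions).
    """
    n = len(images)
    if not (len(masks) == len(doses) == n):
        raise ValueError("images, masks and doses must have equal length")
    sources = list(sources) if sources is not None else ["pet"] * n
    animal_ids = list(animal_ids) if animal_ids is not None else list(range(n))
    if n == 0:
        return pd.DataFrame(columns=["animal", "source", "organ", "pid_g", "suv_max", "snr"])
    organ_set = sorted(masks[0])
    rows = []
    for img, mdict, rec, src, aid in zip(images, masks, doses, sources, animal_ids):
        if sorted(mdict) != organ_set:
            raise ValueError(f"scan {aid!r} has organ set {sorted(mdict)}, expected {organ_set}")
        i_scan = rec.scan_dose()
        for organ in organ_set:
            st = roi_stats(img, mdict[organ])
            rows.append(
                {
                    "animal": aid,
                    "source": src,
                    "organ": organ,
                    "pid_g": percent_id_per_g(st.mean, i_scan, cf),
                    "suv_max": suv_max(st, i_scan, rec.weight),
                    "snr": st.mean / st.sd if st.sd > 0 else np.nan,
                }
            )
    return pd.DataFrame(rows)
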