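"""Clinical metric extraction and patient-level acceptance evaluation.

Per-study semi-quantitative metrics (SUVmean/SUVmax, TBRmean/TBRmax, BTV) are
compared between a test attenuation-correction method and the reference with
paired absolute-or-relative acceptance criteria, the reactive/equivocal/tumor
TBR bands, longitudinal baseline-to-follow-up change concordance, and dynamic
time-activity-curve (TAC) agreement and pattern classification.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .delineation import BTVResult
from .image import ImageVolume, Mask
from .phantom import frame_mid_times_min

__all__ = [
    "ClinicalMetrics",
    "MetricCriterion",
    "AcceptanceCriteria",
    "LongitudinalChange",
    "TAC",
    "clinical_metrics",
    "metric_differences",
    "acceptance_check",
    "tissue_classification",
    "longitudinal_change",
    "longitudinal_concordance",
    "tac_extract",
    "tac_relative_abs_diff",
    "tac_pattern",
]

CLINICAL_METRIC_NAMES = ("tbr_mean", "tbr_max", "btv_ml")


@dataclass
class ClinicalMetrics:
    """Per-study, per-method clinical metric bundle measured within the BTV."""

    suv_mean: float
    suv_max: float
    tbr_mean: float
    tbr_max: float
    btv_ml: float
    peak_location_mm: tuple[float, float, float] | None
    empty: bool = False

    def value(self, name: str) -> float:
        return getattr(self, name)


@dataclass
class MetricCriterion:
    """Paired absolute / relative acceptance thresholds for one metric."""

    abs_threshold: float
    rel_threshold_pct: float

    def __post_init__(self) -> None:
        if self.abs_threshold <= 0 or self.rel_threshold_pct <= 0:
            raise ValueError("acceptance thresholds must be positive")


@dataclass
class AcceptanceCriteria:
    """Clinical acceptance criteria with OR-pass semantics.

    A metric passes when its absolute difference OR its relative difference
    is within bound; the mix reflects that a larger absolute difference is
    acceptable in large or very active tumors.  Defaults: TBRmean +/-0.05 or
    5%, TBRmax +/-0.1 or 5%, BTV +/-2 ml or 10%.
    """

    tbr_mean: MetricCriterion = field(default_factory=lambda: MetricCriterion(0.05, 5.0))
    tbr_max: MetricCriterion = field(default_factory=lambda: MetricCriterion(0.1, 5.0))
    btv_ml: MetricCriterion = field(default_factory=lambda: MetricCriterion(2.0, 10.0))

    def for_metric(self, name: str) -> MetricCriterion:
        return getattr(self, name)


@dataclass
class LongitudinalChange:
    """Baseline-to-follow-up change of the clinical metrics."""

    abs_change: dict[str, float]
    pct_change: dict[str, float]
    direction: dict[str, str]   # up / down / stable


@dataclass
class TAC:
    """A time-activity curve: ROI-mean activity at frame mid-times."""

    mid_times_min: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.mid_times_min = np.asarray(self.mid_times_min, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.mid_times_min.shape != self.values.shape:
            raise ValueError("TAC times and values must have equal length")
        if not (np.diff(self.mid_times_min) > 0).all():
            raise ValueError("TAC times must be strictly increasing")


def clinical_metrics(pet: ImageVolume, tbr: ImageVolume, btv: BTVResult) -> ClinicalMetrics:
    """Mean/max SUV and TBR within the BTV, plus its volume and peak location.

    An empty BTV yields all-zero metrics flagged ``empty`` rather than an
    error, so exclusion bookkeeping stays explicit downstream.
    """
    if not pet.same_grid(tbr):
        raise ValueError("PET and TBR images must share one grid")
    if btv.is_empty:
        return ClinicalMetrics(0.0, 0.0, 0.0, 0.0, 0.0, None, empty=True)
    sel = btv.mask.data
    pet_vals = np.asarray(pet.data, dtype=float)[sel]
    tbr_vals = np.asarray(tbr.data, dtype=float)[sel]
    return ClinicalMetrics(
        suv_mean=float(pet_vals.mean()),
        suv_max=float(pet_vals.max()),
        tbr_mean=float(tbr_vals.mean()),
        tbr_max=float(tbr_vals.max()),
        btv_ml=btv.volume_ml,
        peak_location_mm=btv.peak_location_mm,
    )


def metric_differences(ref: ClinicalMetrics, test: ClinicalMetrics,
                       metrics: tuple[str, ...] = CLINICAL_METRIC_NAMES
                       ) -> dict[str, dict[str, float]]:
    """Absolute (test - ref) and relative percent differences per metric."""
    out: dict[str, dict[str, float]] = {}
    for name in metrics:
        r, t = ref.value(name), test.value(name)
        abs_diff = t - r
        if r > 0:
            rel = 100.0 * abs_diff / r
        else:
            rel = float("nan")
            if t != 0:
                warnings.warn(f"{name}: zero reference value; relative difference undefined")
        out[name] = {"abs_diff": abs_diff, "rel_diff_pct": rel}
    return out


def acceptance_check(diffs: dict[str, dict[str, float]],
                     criteria: AcceptanceCriteria | None = None
                     ) -> dict[str, object]:
    """Classify per-metric differences against the acceptance criteria.

    A metric passes iff |absolute difference| <= absolute threshold OR
    |relative difference| <= relative threshold; the study exceeds the
    criteria iff any metric fails both branches.
    """
    criteria = criteria or AcceptanceCriteria()
    per_metric: dict[str, bool] = {}
    for name, d in diffs.items():
        crit = criteria.for_metric(name)
        abs_ok = abs(d["abs_diff"]) <= crit.abs_threshold
        rel = d["rel_diff_pct"]
        rel_ok = (not np.isnan(rel)) and abs(rel) <= crit.rel_threshold_pct
        per_metric[name] = bool(abs_ok or rel_ok)
    return {"per_metric": per_metric, "exceeds_criteria": not all(per_metric.values())}


def tissue_classification(m: ClinicalMetrics) -> str:
    """Reactive / equivocal / tumor banding of a study's TBR metrics.

    The equivocal band (TBRmax in [2.0, 2.4] or TBRmean in [1.9, 2.1]) is
    carved out first; otherwise tumor requires TBRmax > 2.4 and TBRmean > 2.0,
    and everything else reads as reactive tissue.
    """
    if m.empty:
        raise ValueError("tissue classification requires nonempty BTV metrics")
    if 2.0 <= m.tbr_max <= 2.4 or 1.9 <= m.tbr_mean <= 2.1:
        return "equivocal"
    if m.tbr_max > 2.4 and m.tbr_mean > 2.0:
        return "tumor"
    return "reactive"


def _direction(pct: float, stable_band_pct: float) -> str:
    if abs(pct) < stable_band_pct:
        return "stable"
    return "up" if pct > 0 else "down"


def longitudinal_change(baseline: ClinicalMetrics, followup: ClinicalMetrics,
                        metrics: tuple[str, ...] = CLINICAL_METRIC_NAMES,
                        stable_band_pct: float = 1.0) -> LongitudinalChange:
    """Absolute and percent change of each clinical metric between timepoints."""
    abs_change, pct_change, direction = {}, {}, {}
    for name in metrics:
        b, f = baseline.value(name), followup.value(name)
        if b <= 0:
            raise ValueError(f"{name}: baseline must be positive for percent change")
        abs_change[name] = f - b
        pct_change[name] = 100.0 * (f - b) / b
        direction[name] = _direction(pct_change[name], stable_band_pct)
    return LongitudinalChange(abs_change, pct_change, direction)


def longitudinal_concordance(test: LongitudinalChange, ref: LongitudinalChange,
                             criteria: AcceptanceCriteria | None = None
                             ) -> dict[str, dict[str, bool]]:
    """Concordance of a test method's longitudinal change with the reference.

    Per metric: ``magnitude_within`` iff the percent-change difference is
    within the relative threshold in percentage points OR the absolute-change
    difference is within the absolute threshold (same OR semantics as the
    single-timepoint criteria); ``direction_concordant`` iff the change
    directions agree.
    """
    criteria = criteria or AcceptanceCriteria()
    out: dict[str, dict[str, bool]] = {}
    for name in test.abs_change:
        crit = criteria.for_metric(name)
        d_pct = abs(test.pct_change[name] - ref.pct_change[name])
        d_abs = abs(test.abs_change[name] - ref.abs_change[name])
        out[name] = {
            "magnitude_within": bool(d_pct <= crit.rel_threshold_pct
                                     or d_abs <= crit.abs_threshold),
            "direction_concordant": test.direction[name] == ref.direction[name],
        }
    return out


def tac_extract(frames: ImageVolume, roi: Mask) -> TAC:
    """ROI-mean activity per dynamic frame, at frame mid-times (min)."""
    if frames.data.ndim != 4 or frames.frame_info is None:
        raise ValueError("TAC extraction requires a 4D dynamic series with frame timing")
    if not frames.same_grid(roi):
        raise ValueError("frames and ROI must share one grid")
    if roi.n_voxels == 0:
        raise ValueError("TAC ROI is empty")
    data = np.asarray(frames.data, dtype=float)
    values = data[roi.data, :].mean(axis=0)
    return TAC(mid_times_min=frame_mid_times_min(frames.frame_info), values=values)


def tac_relative_abs_diff(test: TAC, ref: TAC) -> dict[str, object]:
    """Relative absolute difference (%) between two TACs, per frame and summarized."""
    if not np.allclose(test.mid_times_min, ref.mid_times_min):
        raise ValueError("TACs must share one time grid")
    if (ref.values <= 0).any():
        raise ValueError("reference TAC must be strictly positive")
    per_frame = 100.0 * np.abs(test.values - ref.values) / ref.values
    return {
        "per_frame_pct": per_frame,
        "mean_pct": float(per_frame.mean()),
        "sd_pct": float(per_frame.std(ddof=1)) if per_frame.size > 1 else 0.0,
    }


def tac_pattern(tac: TAC, late_start_min: float = 10.0,
                slope_threshold_pct_per_min: float = 0.15) -> str:
    """Classify a TAC as increasing / plateau / decreasing.

    A least-squares slope is fitted to the curve at and after
    ``late_start_min`` and normalized by the late-phase mean, giving a slope
    in %/min; the curve is increasing above the threshold, decreasing below
    its negative, plateau in between.  A quantitative proxy for the visual
    reading used clinically.
    """
    sel = tac.mid_times_min >= late_start_min
    if sel.sum() < 3:
        raise ValueError("TAC pattern needs at least 3 late-phase points")
    t = tac.mid_times_min[sel]
    v = tac.values[sel]
    mean = v.mean()
    if mean <= 0:
        raise ValueError("late-phase TAC mean must be positive")
    slope = np.polyfit(t, v, 1)[0]
    slope_pct = 100.0 * slope / mean
    if slope_pct > slope_threshold_pct_per_min:
        return "increasing"
    if slope_pct < -slope_threshold_pct_per_min:
        return "decreasing"
    return "plateau"
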