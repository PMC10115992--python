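"""End-to-end orchestration: phantom cohort studies and manifest evaluation.

`run_phantom_study` generates a cohort of synthetic head studies (some with
follow-up timepoints, some with attenuation-map artifacts near or far from
the lesion), pushes every study through delineation -> agreement metrics ->
clinical evaluation -> cohort statistics, and writes per-study CSV plus a
summary JSON.  `run_evaluation` runs the identical per-study pipeline on
user-supplied NIfTI volumes listed in a manifest.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import delineation as dl
from . import evaluation as ev
from . import metrics as mx
from .image import ImageVolume, Mask, read_volume
from .phantom import (ArtifactSpec, LesionSpec, Phantom, PhantomSpec,
                      apply_ac_bias, make_dynamic_frames, make_phantom,
                      perturb_mu_map)
from .stats import PairedSample, bland_altman_table

logger = logging.getLogger("aceval")

__all__ = ["RunConfig", "StudyRecord", "ReportBundle",
           "evaluate_study", "run_phantom_study", "run_evaluation"]


@dataclass
class RunConfig:
    """Pipeline parameters; defaults are the protocol's standard values."""

    tbr_threshold: float = 1.6
    min_btv_ml: float = 1.0
    criteria: ev.AcceptanceCriteria = field(default_factory=ev.AcceptanceCriteria)
    proximity_radius_mm: float = 50.0
    shape_fwhm_mm: float = 4.0
    peak_criterion_mm: float = 10.0
    n_angles: int = 8
    hausdorff_percentile: float | None = None

    def __post_init__(self) -> None:
        for name in ("tbr_threshold", "min_btv_ml", "proximity_radius_mm",
                     "shape_fwhm_mm", "peak_criterion_mm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_angles < 1:
            raise ValueError("n_angles must be >= 1")

    def to_dict(self) -> dict:
        d = asdict(self)
        return d


@dataclass
class StudyRecord:
    """One row of a user-data manifest (paths to co-registered NIfTI volumes)."""

    study_id: str
    subject_id: str
    timepoint: str            # "baseline" or "followup"
    ref_mu: str
    ref_pet: str
    test_mu: str
    test_pet: str
    brain_mask: str
    background_roi: str
    head_mask: str | None = None
    exclusion_masks: list[str] = field(default_factory=list)
    fov_mask: str | None = None
    regions: str | None = None
    artifact_category: int | None = None   # manual 1-4 reading, annotation only


@dataclass
class ReportBundle:
    """Cohort outputs: per-study table, agreement table, summaries."""

    studies: pd.DataFrame
    agreement: pd.DataFrame | None
    longitudinal: pd.DataFrame
    tac: pd.DataFrame
    summary: dict
    config: RunConfig

    def write(self, outdir: str | Path) -> Path:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.studies.to_csv(outdir / "studies.csv", index=False)
        if self.agreement is not None:
            self.agreement.to_csv(outdir / "agreement.csv", index=False)
        self.longitudinal.to_csv(outdir / "longitudinal.csv", index=False)
        self.tac.to_csv(outdir / "tac.csv", index=False)
        payload = {"config": self.config.to_dict(), **self.summary}
        with open(outdir / "summary.json", "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
        return outdir


def evaluate_study(*, ref_mu: ImageVolume, test_mu: ImageVolume,
                   ref_pet: ImageVolume, test_pet: ImageVolume,
                   head: Mask, brain: Mask, background_roi: Mask,
                   exclusions: list[Mask] | None = None,
                   regions: ImageVolume | None = None,
                   fov: Mask | None = None,
                   config: RunConfig | None = None) -> dict:
    """Run the full per-study evaluation of one test method vs the reference.

    Attenuation-map metrics are always computed; PET metrics only when the
    reference BTV exceeds the inclusion volume.  Returns a flat record.
    """
    config = config or RunConfig()
    excl = exclusions or []
    row: dict = {}

    ref_classes = mx.classify_mu(ref_mu, head, fov=fov)
    test_classes = mx.classify_mu(test_mu, head, fov=fov)
    row["dice_tissue"] = mx.class_dice(ref_classes, test_classes, mx.CLASS_TISSUE)
    row["dice_bone"] = mx.class_dice(ref_classes, test_classes, mx.CLASS_BONE)
    sim = mx.mu_similarity(ref_mu, test_mu, head)
    row["mae_mu"], row["ssim_mu"] = sim["mae"], sim["ssim"]

    ref_bg = dl.compute_background_mean(ref_pet, background_roi)
    ref_btv = dl.delineate_btv(ref_pet, ref_bg, brain, excl, config.tbr_threshold)
    row["ref_btv_ml"] = ref_btv.volume_ml
    row["included"] = dl.btv_inclusion(ref_btv, config.min_btv_ml)
    if not row["included"]:
        logger.info("reference BTV %.2f ml <= %.1f ml: study excluded from PET evaluation",
                    ref_btv.volume_ml, config.min_btv_ml)
        return row

    prox = mx.proximity_sphere(ref_btv, config.proximity_radius_mm)
    row["dice_tissue_proximal"] = mx.class_dice(ref_classes, test_classes,
                                                mx.CLASS_TISSUE, within=prox)
    row["dice_bone_proximal"] = mx.class_dice(ref_classes, test_classes,
                                              mx.CLASS_BONE, within=prox)

    test_bg = dl.compute_background_mean(test_pet, background_roi)
    test_btv = dl.delineate_btv(test_pet, test_bg, brain, excl, config.tbr_threshold)
    row["test_btv_ml"] = test_btv.volume_ml

    ref_cm = ev.clinical_metrics(ref_pet, ref_btv.tbr, ref_btv)
    test_cm = ev.clinical_metrics(test_pet, test_btv.tbr, test_btv)
    for prefix, cm in (("ref", ref_cm), ("test", test_cm)):
        for name in ("suv_mean", "suv_max", "tbr_mean", "tbr_max", "btv_ml"):
            row[f"{prefix}_{name}"] = cm.value(name)
    row["test_btv_empty"] = test_cm.empty

    if not test_cm.empty:
        diffs = ev.metric_differences(ref_cm, test_cm)
        for name, d in diffs.items():
            row[f"{name}_abs_diff"] = d["abs_diff"]
            row[f"{name}_rel_diff_pct"] = d["rel_diff_pct"]
        check = ev.acceptance_check(diffs, config.criteria)
        for name, ok in check["per_metric"].items():
            row[f"{name}_pass"] = ok
        row["exceeds_criteria"] = check["exceeds_criteria"]
        row["ref_class"] = ev.tissue_classification(ref_cm)
        row["test_class"] = ev.tissue_classification(test_cm)
        row["class_concordant"] = row["ref_class"] == row["test_class"]
        contour = mx.contour_agreement(ref_btv.mask, test_btv.mask,
                                       percentile=config.hausdorff_percentile)
        row["contour_dice"], row["hausdorff_mm"] = contour["dice"], contour["hausdorff_mm"]
        pk = mx.peak_distance(ref_btv, test_btv, config.peak_criterion_mm)
        row["peak_distance_mm"] = pk["distance_mm"]
        row["peak_within_criterion"] = pk["within_criterion"]
    else:
        row["exceeds_criteria"] = True   # losing the tumor certainly exceeds
        logger.warning("test BTV empty while reference BTV is %.2f ml", ref_btv.volume_ml)
    row["shape_deviation_ml"] = mx.shape_deviation(ref_btv.mask, test_btv.mask,
                                                   config.shape_fwhm_mm)
    psim = mx.pet_similarity(ref_pet, test_pet, brain)
    row["pet_mae"], row["pet_ssim"], row["pet_psnr"] = psim["mae"], psim["ssim"], psim["psnr"]
    if regions is not None:
        for label, pct in mx.regional_differences(ref_pet, test_pet, regions).items():
            row[f"region_{label}_pct"] = pct
    return row


# ---------------------------------------------------------------------------
# phantom cohort
# ---------------------------------------------------------------------------

TAC_PATTERNS = ("increasing", "plateau", "decreasing")


def _draw_subject(rng: np.random.Generator, grid_shape, spacing) -> dict:
    """Random subject-level phantom parameters (lesion, follow-up, artifacts)."""
    small = rng.random() < 0.15
    radius = float(rng.uniform(4.0, 5.0) if small else rng.uniform(8.0, 15.0))
    tbr = float(rng.uniform(1.9, 3.2))
    side = 1.0 if rng.random() < 0.5 else -1.0
    center = (side * float(rng.uniform(18.0, 34.0)),
              float(rng.uniform(-20.0, 24.0)),
              float(rng.uniform(-8.0, 22.0)))
    has_followup = rng.random() < 0.4
    followup_factor = float(rng.uniform(0.75, 1.25))
    scenario = rng.choice(["none", "far", "near"], p=[0.5, 0.25, 0.25])
    artifacts: list[ArtifactSpec] = []
    if scenario != "none":
        kind = str(rng.choice(["false_bone_patch", "metal_void"]))
        size = float(rng.uniform(6.0, 12.0))
        if scenario == "near":
            offset = rng.normal(size=3)
            offset = offset / np.linalg.norm(offset) * (radius + size + 4.0)
        else:
            # opposite hemisphere, well clear of the lesion
            offset = np.array([-2.2 * center[0], -center[1] * 0.5, 0.0])
        art_center = tuple(float(c + o) for c, o in zip(center, offset))
        artifacts.append(ArtifactSpec(kind=kind, center_mm=art_center, size_mm=size))
    return {"radius": radius, "tbr": tbr, "center": center,
            "has_followup": has_followup, "followup_factor": followup_factor,
            "artifacts": artifacts, "scenario": scenario}


def _simulate_study(subject: dict, timepoint: str, study_seed: int,
                    config: RunConfig, identity: bool,
                    grid_shape, spacing) -> tuple[Phantom, ImageVolume, ImageVolume, ImageVolume]:
    """Build phantom + (ref PET, test mu, test PET) for one timepoint."""
    radius = subject["radius"]
    if timepoint == "followup":
        radius *= subject["followup_factor"]
    spec = PhantomSpec(
        shape=tuple(grid_shape), spacing=tuple(spacing),
        lesions=[LesionSpec(center_mm=subject["center"], radius_mm=radius,
                            tbr=subject["tbr"])],
        seed=study_seed,
    )
    phantom = make_phantom(spec)
    ref_pet = phantom.activity
    if identity or not subject["artifacts"]:
        test_mu = phantom.mu_map.with_data(phantom.mu_map.data.copy())
    else:
        test_mu = perturb_mu_map(phantom, subject["artifacts"])
    test_pet = apply_ac_bias(ref_pet, phantom.mu_map, test_mu, config.n_angles)
    return phantom, ref_pet, test_mu, test_pet


def run_phantom_study(config: RunConfig | None = None, n_subjects: int = 20,
                      seed: int = 0, identity: bool = False,
                      n_dynamic: int = 3,
                      grid_shape: tuple[int, int, int] = (96, 96, 96),
                      spacing: tuple[float, float, float] = (2.0, 2.0, 2.0),
                      outdir: str | Path | None = None) -> ReportBundle:
    """Generate and evaluate a synthetic cohort; fully seed-deterministic.

    ``identity=True`` evaluates the reference mu-map against itself (the
    null pipeline); otherwise each subject's test mu-map may carry a random
    surgical artifact near or far from the lesion.  A subset of baseline
    studies also gets a 14-frame dynamic series with a rotating TAC pattern.
    """
    config = config or RunConfig()
    rng = np.random.default_rng(seed)
    subject_seeds = rng.integers(0, 2**31 - 1, size=(n_subjects, 2))
    rows, long_rows, tac_rows = [], [], []
    n_dynamic_done = 0

    for i in range(n_subjects):
        subject = _draw_subject(rng, grid_shape, spacing)
        timepoints = ["baseline"] + (["followup"] if subject["has_followup"] else [])
        changes: dict[str, dict] = {}
        for t_idx, timepoint in enumerate(timepoints):
            study_seed = int(subject_seeds[i, t_idx])
            phantom, ref_pet, test_mu, test_pet = _simulate_study(
                subject, timepoint, study_seed, config, identity, grid_shape, spacing)
            row = {
                "subject_id": f"S{i:03d}", "study_id": f"S{i:03d}_{timepoint}",
                "timepoint": timepoint, "method": "identity" if identity else "mrac",
                "artifact_scenario": "none" if identity else subject["scenario"],
            }
            row.update(evaluate_study(
                ref_mu=phantom.mu_map, test_mu=test_mu, ref_pet=ref_pet,
                test_pet=test_pet, head=phantom.head_mask, brain=phantom.brain_mask,
                background_roi=phantom.background_roi,
                regions=phantom.region_labels, config=config))
            rows.append(row)
            if row["included"] and not row.get("test_btv_empty", True):
                changes[timepoint] = {
                    "ref": ev.ClinicalMetrics(row["ref_suv_mean"], row["ref_suv_max"],
                                              row["ref_tbr_mean"], row["ref_tbr_max"],
                                              row["ref_btv_ml"], None),
                    "test": ev.ClinicalMetrics(row["test_suv_mean"], row["test_suv_max"],
                                               row["test_tbr_mean"], row["test_tbr_max"],
                                               row["test_btv_ml"], None),
                }
            # dynamic series for the first included baseline studies
            if (timepoint == "baseline" and row["included"]
                    and n_dynamic_done < n_dynamic):
                pattern = TAC_PATTERNS[n_dynamic_done % len(TAC_PATTERNS)]
                frames = make_dynamic_frames(phantom, pattern=pattern)
                test_frames = apply_ac_bias(frames, phantom.mu_map, test_mu,
                                            config.n_angles)
                roi = phantom.true_btv_mask
                ref_tac = ev.tac_extract(frames, roi)
                test_tac = ev.tac_extract(test_frames, roi)
                diff = ev.tac_relative_abs_diff(test_tac, ref_tac)
                tac_rows.append({
                    "subject_id": f"S{i:03d}", "pattern_generated": pattern,
                    "ref_pattern": ev.tac_pattern(ref_tac),
                    "test_pattern": ev.tac_pattern(test_tac),
                    "mean_abs_diff_pct": diff["mean_pct"],
                    "sd_abs_diff_pct": diff["sd_pct"],
                })
                n_dynamic_done += 1
        if len(changes) == 2:
            ref_change = ev.longitudinal_change(changes["baseline"]["ref"],
                                                changes["followup"]["ref"])
            test_change = ev.longitudinal_change(changes["baseline"]["test"],
                                                 changes["followup"]["test"])
            conc = ev.longitudinal_concordance(test_change, ref_change, config.criteria)
            lrow = {"subject_id": f"S{i:03d}"}
            for name in ev.CLINICAL_METRIC_NAMES:
                lrow[f"{name}_ref_pct_change"] = ref_change.pct_change[name]
                lrow[f"{name}_test_pct_change"] = test_change.pct_change[name]
                lrow[f"{name}_magnitude_within"] = conc[name]["magnitude_within"]
                lrow[f"{name}_direction_concordant"] = conc[name]["direction_concordant"]
            long_rows.append(lrow)

    studies = pd.DataFrame(rows)
    longitudinal = pd.DataFrame(long_rows)
    tac = pd.DataFrame(tac_rows)
    agreement = _cohort_agreement(studies)
    summary = _summarize(studies, longitudinal, tac)
    bundle = ReportBundle(studies=studies, agreement=agreement,
                          longitudinal=longitudinal, tac=tac,
                          summary=summary, config=config)
    if outdir is not None:
        bundle.write(outdir)
    return bundle


def _cohort_agreement(studies: pd.DataFrame) -> pd.DataFrame | None:
    """Bland-Altman table over included studies with nonempty test BTV."""
    ok = studies[studies.get("included", pd.Series(dtype=bool)) == True]  # noqa: E712
    if "test_btv_empty" in ok.columns:
        ok = ok[ok["test_btv_empty"] == False]  # noqa: E712
    samples = {}
    for name in ev.CLINICAL_METRIC_NAMES:
        ref_col, test_col = f"ref_{name}", f"test_{name}"
        if ref_col not in ok.columns or len(ok) < 2:
            continue
        sub = ok[(ok[ref_col] > 0) & (ok[test_col] > 0)]
        if len(sub) < 2 or sub["subject_id"].nunique() < 2:
            continue
        samples[name] = PairedSample(subject=sub["subject_id"].to_numpy(),
                                     ref=sub[ref_col].to_numpy(),
                                     test=sub[test_col].to_numpy())
    if not samples:
        return None
    return bland_altman_table(samples)


def _summarize(studies: pd.DataFrame, longitudinal: pd.DataFrame,
               tac: pd.DataFrame) -> dict:
    included = studies[studies["included"] == True] if "included" in studies else studies  # noqa: E712
    summary: dict = {
        "n_studies": int(len(studies)),
        "n_included": int(len(included)),
        "n_excluded_small_btv": int(len(studies) - len(included)),
        "dice_tissue_mean": float(studies["dice_tissue"].mean()),
        "dice_bone_mean": float(studies["dice_bone"].mean()),
    }
    if "exceeds_criteria" in included.columns and len(included):
        summary["n_exceeding_criteria"] = int(included["exceeds_criteria"].sum())
    if "peak_within_criterion" in included.columns:
        pk = included["peak_within_criterion"].dropna()
        if len(pk):
            summary["peak_within_criterion_frac"] = float(pk.mean())
    if "class_concordant" in included.columns:
        cc = included["class_concordant"].dropna()
        if len(cc):
            summary["class_concordant_frac"] = float(cc.mean())
    if len(longitudinal):
        for name in ev.CLINICAL_METRIC_NAMES:
            col = f"{name}_direction_concordant"
            if col in longitudinal.columns:
                summary[f"longitudinal_{name}_direction_concordant_frac"] = \
                    float(longitudinal[col].mean())
    if len(tac):
        summary["tac_mean_abs_diff_pct"] = float(tac["mean_abs_diff_pct"].mean())
        summary["tac_pattern_concordant_frac"] = float(
            (tac["ref_pattern"] == tac["test_pattern"]).mean())
    return summary


# ---------------------------------------------------------------------------
# manifest evaluation
# ---------------------------------------------------------------------------

def load_manifest(path: str | Path) -> list[StudyRecord]:
    """Read a CSV or JSON manifest into study records."""
    path = Path(path)
    if path.suffix == ".json":
        with open(path) as fh:
            raw = json.load(fh)
    else:
        raw = pd.read_csv(path).to_dict(orient="records")
    records = []
    for entry in raw:
        entry = {k: v for k, v in entry.items() if not pd.isna(v)} \
            if not isinstance(entry.get("exclusion_masks"), list) else entry
        excl = entry.get("exclusion_masks", [])
        if isinstance(excl, str):
            excl = [p for p in excl.split(";") if p]
        entry["exclusion_masks"] = excl
        records.append(StudyRecord(**entry))
    return records


def _load_mask(path: str, label: str) -> Mask:
    vol = read_volume(path)
    return Mask(data=vol.data > 0.5, spacing=vol.spacing, origin=vol.origin,
                label=label)


def run_evaluation(manifest: list[StudyRecord] | str | Path,
                   config: RunConfig | None = None,
                   outdir: str | Path | None = None) -> ReportBundle:
    """Run the per-study pipeline on user data listed in a manifest."""
    config = config or RunConfig()
    if not isinstance(manifest, list):
        manifest = load_manifest(manifest)
    rows = []
    for rec in manifest:
        brain = _load_mask(rec.brain_mask, "brain")
        head = _load_mask(rec.head_mask, "head") if rec.head_mask else brain
        fov = _load_mask(rec.fov_mask, "fov") if rec.fov_mask else None
        excl = [_load_mask(p, "exclusion") for p in rec.exclusion_masks]
        regions = read_volume(rec.regions) if rec.regions else None
        test_mu = read_volume(rec.test_mu)
        if fov is not None:
            test_mu = dl.apply_fov_superimposition(test_mu, read_volume(rec.ref_mu), fov)
            logger.info("%s: FOV superimposition applied", rec.study_id)
        row = {"subject_id": rec.subject_id, "study_id": rec.study_id,
               "timepoint": rec.timepoint, "method": "test",
               "artifact_category": rec.artifact_category}
        row.update(evaluate_study(
            ref_mu=read_volume(rec.ref_mu), test_mu=test_mu,
            ref_pet=read_volume(rec.ref_pet), test_pet=read_volume(rec.test_pet),
            head=head, brain=brain, background_roi=_load_mask(rec.background_roi,
                                                              "background_roi"),
            exclusions=excl, regions=regions, config=config))
        rows.append(row)
    studies = pd.DataFrame(rows)
    bundle = ReportBundle(studies=studies, agreement=_cohort_agreement(studies),
                          longitudinal=pd.DataFrame(), tac=pd.DataFrame(),
                          summary=_summarize(studies, pd.DataFrame(), pd.DataFrame()),
                          config=config)
    if outdir is not None:
        bundle.write(outdir)
    return bundle
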