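"""Per-lesion and cohort orchestration of the full analysis chain.

One lesion is one work unit: calibrate against the reference muscle, select
the analysis slice, segment the hyperperfused core, fit the serpentine
margin band, compute the margin mean-FD time curve, extract FDmax and
ADC_25, and predict the pooled grade group. A cohort of lesion records is
then summarized with the full diagnostic-accuracy layer (per pooled
comparison and per zone subgroup).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any, Optional, Sequence

import numpy as np
import pandas as pd

from . import diagstats, fractal, grading, preprocess, temporal
from .errors import EmptyCoreError, InputError
from .grading import LesionRecord, ThresholdTable
from .margin import CoreMask, MarginBand, margin_band, segment_core
from .preprocess import DceSeries, MuscleRoi


@dataclass
class RunConfig:
    """Every knob of the pipeline, serializable to/from a dict (YAML)."""

    scales: tuple[int, ...] = fractal.DEFAULT_SCALES
    kernel: int = 3
    connectivity: int = 4
    band_width_mm: float = 3.0
    band_side: str = "straddle"
    rel_threshold: float = 0.6
    spatial_scale_mm: float = preprocess.DEFAULT_SPATIAL_SD_MM
    range_factor: float = preprocess.DEFAULT_RANGE_FACTOR
    per_frame_adjust: bool = False
    slice_index: Optional[int] = None  # None -> automatic paramedian choice
    significance_rule: str = "pirads_and_fd"
    thresholds: ThresholdTable = field(default_factory=ThresholdTable)
    seed: int = 0
    outdir: Optional[str] = None

    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        d["scales"] = list(self.scales)
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "RunConfig":
        d = dict(d)
        if "scales" in d:
            d["scales"] = tuple(d["scales"])
        if isinstance(d.get("thresholds"), dict):
            d["thresholds"] = ThresholdTable(**d["thresholds"])
        return cls(**d)

    def save(self, path: str | Path) -> None:
        import yaml

        Path(path).write_text(yaml.safe_dump(self.to_dict()))

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        import yaml

        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass
class LesionInputs:
    """Everything the per-lesion chain consumes."""

    series: DceSeries  # raw
    muscle_roi: Optional[MuscleRoi]
    prostate: np.ndarray  # (z, y, x) bool
    capsule: Optional[np.ndarray]  # (z, y, x) bool
    seed_point: tuple[int, int]  # (y, x)
    adc: Optional[np.ndarray] = None
    adc_hotspot: Optional[np.ndarray] = None
    pirads: Optional[int] = None
    isup_ref: Optional[int] = None
    zone: str = "peripheral"
    lesion_id: str = "lesion"


@dataclass
class LesionArtifacts:
    """Intermediates kept for QC and export."""

    record: LesionRecord
    curve: temporal.FdTimeCurve
    core: CoreMask
    band: MarginBand
    fd_map_argmax: fractal.FdMap
    slice_index: int
    ref_frame: int
    sigma: float


def _reference_frame(series: DceSeries, z: int, seed: tuple[int, int],
                     inner_mm: float = 4.0, outer_mm: tuple[float, float] = (15.0, 21.0)) -> int:
    """Frame on which the enhancing lesion stands out most from background:
    maximizes the median intensity in a small disk at the seed minus the
    median in a surrounding reference annulus (robust to local texture)."""
    dy, dx = series.in_plane_spacing
    yy = (np.arange(series.data.shape[2])[:, None] - seed[0]) * dy
    xx = (np.arange(series.data.shape[3])[None, :] - seed[1]) * dx
    r2 = yy * yy + xx * xx
    inner = r2 <= inner_mm**2
    annulus = (r2 >= outer_mm[0] ** 2) & (r2 <= outer_mm[1] ** 2)
    if not annulus.any():
        annulus = ~inner
    frames = series.data[:, z]
    inner_vals = frames[:, inner]
    med_inner = np.median(inner_vals, axis=1)
    # penalize frames where the seed region is speckled rather than
    # uniformly enhancing (median absolute deviation)
    mad_inner = np.median(np.abs(inner_vals - med_inner[:, None]), axis=1)
    score = med_inner - np.median(frames[:, annulus], axis=1) - mad_inner
    return int(np.argmax(score))


def _select_slice(series: DceSeries, config: RunConfig, inputs: LesionInputs,
                  sigma: float) -> tuple[int, int, CoreMask]:
    """Paramedian slice choice: segment the core on every slice where that
    succeeds and take the largest core area excluding the central (largest)
    slice; ties break toward the lower index."""
    if config.slice_index is not None:
        z = config.slice_index
        t_ref = _reference_frame(series, z, inputs.seed_point)
        core = _segment_on(series, z, t_ref, config, inputs, sigma)
        return z, t_ref, core
    candidates: list[tuple[int, int, CoreMask]] = []
    for z in range(series.data.shape[1]):
        try:
            t_ref = _reference_frame(series, z, inputs.seed_point)
            core = _segment_on(series, z, t_ref, config, inputs, sigma)
        except EmptyCoreError:
            continue
        candidates.append((z, t_ref, core))
    if not candidates:
        raise EmptyCoreError("core segmentation failed on every slice")
    if len(candidates) == 1:
        return candidates[0]
    areas = [c[2].mask.sum() for c in candidates]
    central = int(np.argmax(areas))
    rest = [c for i, c in enumerate(candidates) if i != central]
    rest_areas = [c[2].mask.sum() for c in rest]
    return rest[int(np.argmax(rest_areas))]


def _segment_on(series: DceSeries, z: int, t_ref: int, config: RunConfig,
                inputs: LesionInputs, sigma: float) -> CoreMask:
    frame = preprocess.denoise(
        series.data[t_ref, z], sigma,
        spatial_scale_mm=config.spatial_scale_mm,
        pixel_spacing_mm=series.in_plane_spacing[1],
        range_factor=config.range_factor,
    )
    return segment_core(frame, inputs.seed_point, rel_threshold=config.rel_threshold,
                        spacing=series.in_plane_spacing, slice_index=z)


def run_lesion(config: RunConfig, inputs: LesionInputs) -> LesionArtifacts:
    """Execute the full per-lesion chain and return the record plus QC
    intermediates. Raises a stage-specific error on failure."""
    if inputs.muscle_roi is None:
        raise InputError("calibration stage requires a muscle ROI (none provided)")
    sigma = preprocess.estimate_noise(inputs.series, inputs.muscle_roi)
    series = preprocess.calibrate(inputs.series, inputs.muscle_roi)

    z, t_ref, core = _select_slice(series, config, inputs, series.sigma)
    capsule_slice = inputs.capsule[z] if inputs.capsule is not None else None
    band = margin_band(core, inputs.prostate[z], capsule_slice,
                       spacing=series.in_plane_spacing,
                       width_mm=config.band_width_mm, side=config.band_side)
    curve = temporal.fd_time_curve(
        series, band, per_frame_adjust=config.per_frame_adjust, ref_frame=t_ref,
        kernel=config.kernel, scales=config.scales, connectivity=config.connectivity,
        spatial_scale_mm=config.spatial_scale_mm,
    )
    fdmax, t_max = temporal.max_fd(curve)

    adc_25 = None
    if inputs.adc is not None and inputs.adc_hotspot is not None:
        adc_25 = grading.adc25(inputs.adc, inputs.adc_hotspot)
    record = LesionRecord(
        lesion_id=inputs.lesion_id, fdmax=fdmax, adc25=adc_25,
        pirads=inputs.pirads, isup_ref=inputs.isup_ref, zone=inputs.zone,
        pred_group=grading.predict_group_fd(fdmax, config.thresholds),
    )
    frame_at_max = preprocess.denoise(
        series.data[t_max, z], series.sigma,
        spatial_scale_mm=config.spatial_scale_mm,
        pixel_spacing_mm=series.in_plane_spacing[1],
        range_factor=config.range_factor,
    )
    fd_map = fractal.local_fd_map(frame_at_max, kernel=config.kernel,
                                  scales=config.scales, connectivity=config.connectivity,
                                  timepoint=t_max)
    artifacts = LesionArtifacts(record=record, curve=curve, core=core, band=band,
                                fd_map_argmax=fd_map, slice_index=z, ref_frame=t_ref,
                                sigma=sigma)
    if config.outdir is not None:
        export_lesion(config, inputs, series, artifacts)
    return artifacts


def export_lesion(config: RunConfig, inputs: LesionInputs, series: DceSeries,
                  artifacts: LesionArtifacts) -> Path:
    """Write QC artifacts (FD map NIfTI, curve CSV, band overlay PNG, config)."""
    from . import io as fio

    outdir = Path(config.outdir) / inputs.lesion_id
    outdir.mkdir(parents=True, exist_ok=True)
    fio.write_fd_map(artifacts.fd_map_argmax, series.in_plane_spacing,
                     outdir / "fd_map_argmax.nii.gz")
    artifacts.curve.to_frame().to_csv(outdir / "fd_time_curve.csv", index=False)
    config.save(outdir / "config.yaml")
    pd.DataFrame([asdict(artifacts.record)]).to_csv(outdir / "lesion.csv", index=False)
    try:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(5, 5))
        z, t = artifacts.slice_index, artifacts.ref_frame
        ax.imshow(series.data[t, z], cmap="gray")
        overlay = np.zeros((*artifacts.band.mask.shape, 4))
        overlay[artifacts.band.mask] = (1.0, 0.2, 0.1, 0.6)
        ax.imshow(overlay)
        ax.set_title(f"{inputs.lesion_id}: margin band, slice {z}, frame {t}")
        ax.axis("off")
        fig.savefig(outdir / "band_overlay.png", dpi=120)
        plt.close(fig)
    except Exception:  # plotting is best-effort QC
        pass
    return outdir


# ---------------------------------------------------------------------------
# cohort level

POOLED_COMPARISONS = (
    ("1 versus 2-5", 2),
    ("1-2 versus 3-5", 3),
    ("1-3 versus 4-5", 4),
)


@dataclass
class CohortReport:
    """Table-2-style diagnostic summary of a lesion cohort."""

    table: pd.DataFrame
    kappa_fd: Optional[float]
    kappa_fd_ci: Optional[tuple[float, float]]
    group_tests: Optional[diagstats.GroupTestResult]
    zone_test_p: Optional[float]
    records: pd.DataFrame

    def save(self, outdir: str | Path) -> Path:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.table.to_csv(outdir / "cohort_table.csv", index=False)
        self.records.to_csv(outdir / "lesions.csv", index=False)
        return outdir


def _fmt_prop(est: Optional[diagstats.ProportionEstimate]) -> dict[str, Any]:
    if est is None:
        return {"pct": None, "ci_low_pct": None, "ci_high_pct": None, "counts": None}
    pt, lo, hi = est.rounded()
    return {"pct": pt, "ci_low_pct": lo, "ci_high_pct": hi,
            "counts": f"{est.numerator}/{est.denominator}"}


def run_cohort(config: RunConfig, records: Sequence[LesionRecord]) -> CohortReport:
    """Aggregate lesion records into the diagnostic-accuracy report.

    For every pooled grade comparison: AUC of FDmax (rank estimator, DeLong
    CI), the configured FD cutoff, sensitivity and specificity with exact
    CIs; the ADC_25 row for the 1-versus-2-5 pool where ADC values exist.
    Adds quadratic-weighted kappa for the multi-class prediction, group
    tests of FDmax by reference grade, and the zone subgroup comparison.
    Cohorts with a single reference class leave the statistics undefined.
    """
    if len(records) < 2:
        raise InputError("need at least two lesions for a cohort report")
    df = pd.DataFrame([asdict(r) for r in records])
    thr = config.thresholds
    cutoffs = {2: thr.c1, 3: thr.c2, 4: thr.c3}
    rows = []
    has_ref = df["isup_ref"].notna()
    graded = df[has_ref].copy()
    multi_class = graded["isup_ref"].nunique() > 1 if not graded.empty else False

    for pool_name, split in POOLED_COMPARISONS:
        row: dict[str, Any] = {"comparison": pool_name, "modality": "fd",
                               "cutoff": cutoffs[split]}
        if multi_class and (graded["isup_ref"] >= split).nunique() == 2:
            ref = graded["isup_ref"].to_numpy(dtype=int)
            pred = graded["pred_group"].to_numpy(dtype=int)
            counts = diagstats.pooled_counts(np.where(pred >= split, split, 1),
                                             np.where(ref >= split, split, 1),
                                             split=split, pool=pool_name)
            sens, spec = diagstats.sens_spec(counts)
            auc, auc_ci = diagstats.roc_auc(graded["fdmax"], ref >= split)
            row.update({"auc": auc, "auc_ci_low": auc_ci[0], "auc_ci_high": auc_ci[1]})
            row.update({f"sens_{k}": v for k, v in _fmt_prop(sens).items()})
            row.update({f"spec_{k}": v for k, v in _fmt_prop(spec).items()})
        rows.append(row)

    if df["adc25"].notna().any() and multi_class:
        sub = graded[graded["adc25"].notna()]
        if (sub["isup_ref"] >= 2).nunique() == 2:
            ref = sub["isup_ref"].to_numpy(dtype=int)
            called = sub["adc25"].to_numpy() < thr.adc_cutoff
            counts = diagstats.ConfusionCounts(
                tp=int(np.sum((ref >= 2) & called)), fn=int(np.sum((ref >= 2) & ~called)),
                tn=int(np.sum((ref < 2) & ~called)), fp=int(np.sum((ref < 2) & called)),
                pool="1 versus 2-5 (ADC)")
            sens, spec = diagstats.sens_spec(counts)
            auc, auc_ci = diagstats.roc_auc(-sub["adc25"].to_numpy(), ref >= 2)
            row = {"comparison": "1 versus 2-5", "modality": "adc25",
                   "cutoff": thr.adc_cutoff, "auc": auc,
                   "auc_ci_low": auc_ci[0], "auc_ci_high": auc_ci[1]}
            row.update({f"sens_{k}": v for k, v in _fmt_prop(sens).items()})
            row.update({f"spec_{k}": v for k, v in _fmt_prop(spec).items()})
            rows.append(row)

    kappa = kappa_ci = None
    gt = None
    zone_p = None
    if multi_class:
        ref_capped = np.minimum(graded["isup_ref"].to_numpy(dtype=int), 4)
        kappa, kappa_ci = diagstats.weighted_kappa(
            graded["pred_group"].to_numpy(dtype=int), ref_capped,
            weighting="quadratic", seed=config.seed, ci=True)
        groups = {g: sub["fdmax"].to_numpy()
                  for g, sub in graded.groupby("isup_ref") if len(sub) > 0}
        if len(groups) >= 2:
            gt = diagstats.group_tests(groups)
    zones = {z: sub["fdmax"].to_numpy() for z, sub in df.groupby("zone")}
    if len(zones) >= 2:
        zone_p = diagstats.group_tests(zones).kruskal_p

    report = CohortReport(table=pd.DataFrame(rows), kappa_fd=kappa, kappa_fd_ci=kappa_ci,
                          group_tests=gt, zone_test_p=zone_p, records=df)
    if config.outdir is not None:
        report.save(Path(config.outdir))
    return report
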