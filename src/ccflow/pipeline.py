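"""End-to-end orchestration: manifest -> compensation -> binarization ->
corner-ROI metrics -> per-eye averages -> group tables.

Deterministic given inputs and configuration: the pipeline itself draws
no random numbers. Per-eye failures (unreadable or mismatched images)
are logged and skipped; an empty surviving cohort aborts the run.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .binarization import ThresholdParams, segment_flow_deficits
from .compensation import CompensationParams, compensate_flow
from .fd_metrics import (
    CORNERS,
    EyeRecord,
    average_eye_metrics,
    corner_metrics,
)
from .group_stats import comparisons_to_frame, summarize_groups
from .image_io import CohortManifest, read_enface

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "process_eye"]

log = logging.getLogger("ccflow")


@dataclass
class PipelineConfig:
    """Run configuration; defaults reproduce the standard analysis."""

    radii_px: tuple[int, ...] = (4, 8)
    compensation: CompensationParams = field(default_factory=CompensationParams)
    threshold_k: float = 0.25
    threshold_p: float = 2.0
    threshold_q: float = 10.0
    threshold_r_dyn: float = 0.5
    roi_size_mm: float = 1.0
    group_test: str = "wilcoxon_signed_rank"
    mnv_test: str = "mann_whitney_u"
    qc_panels: bool = False
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not self.radii_px or any(r < 1 for r in self.radii_px):
            raise ValueError("radii_px must be a nonempty list of integers >= 1")
        self.radii_px = tuple(int(r) for r in self.radii_px)

    def threshold_params(self, radius_px: int) -> ThresholdParams:
        return ThresholdParams(
            radius_px=radius_px,
            k=self.threshold_k,
            p=self.threshold_p,
            q=self.threshold_q,
            r_dyn=self.threshold_r_dyn,
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        comp = raw.pop("compensation", None)
        cfg = cls(**raw)
        if comp is not None:
            cfg.compensation = CompensationParams(**comp)
        return cfg


@dataclass
class PipelineResult:
    per_eye: pd.DataFrame
    records: list[EyeRecord]
    tables: dict[str, pd.DataFrame]  # e.g. "metrics_r4", "corners_r4", "mnv_fd_percent"
    failed_eyes: list[str]
    out_dir: Path | None


def process_eye(row, config: PipelineConfig) -> EyeRecord:
    """Run the image chain for one manifest row."""
    flow = read_enface(row.flow_path, row.pixel_pitch_um, "flow", row.eye_id)
    structure = read_enface(row.structure_path, row.pixel_pitch_um, "structure", row.eye_id)
    compensated = compensate_flow(flow, structure, config.compensation)
    per_radius_corners = {}
    per_radius_avg = {}
    for radius in config.radii_px:
        mask = segment_flow_deficits(compensated, config.threshold_params(radius))
        metrics = corner_metrics(mask, size_mm=config.roi_size_mm)
        per_radius_corners[radius] = metrics
        per_radius_avg[radius] = average_eye_metrics(metrics)
    return EyeRecord(
        eye_id=row.eye_id,
        group=row.group,
        mnv_status=row.mnv_status,
        corner_metrics=per_radius_corners,
        averages=per_radius_avg,
    )


def _per_eye_frame(records: list[EyeRecord], radii: tuple[int, ...]) -> pd.DataFrame:
    rows = []
    for rec in records:
        for radius in radii:
            row = {
                "eye_id": rec.eye_id,
                "group": rec.group,
                "mnv_status": rec.mnv_status,
                "radius_px": radius,
            }
            for corner in CORNERS:
                m = rec.corner_metrics[radius][corner]
                row[f"{corner}_fd_percent"] = m.fd_percent
                row[f"{corner}_n_fd"] = m.n_fd
                row[f"{corner}_mean_fd_size_um2"] = m.mean_fd_size_um2
                row[f"{corner}_total_fd_area_mm2"] = m.total_fd_area_mm2
            avg = rec.averages[radius]
            row["avg_fd_percent"] = avg.fd_percent
            row["avg_n_fd"] = avg.n_fd
            row["avg_mean_fd_size_um2"] = avg.mean_fd_size_um2
            row["avg_total_fd_area_mm2"] = avg.total_fd_area_mm2
            rows.append(row)
    return pd.DataFrame(rows)


def _qc_panel(row, config: PipelineConfig, out_dir: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    flow = read_enface(row.flow_path, row.pixel_pitch_um, "flow", row.eye_id)
    structure = read_enface(row.structure_path, row.pixel_pitch_um, "structure", row.eye_id)
    compensated = compensate_flow(flow, structure, config.compensation)
    n_panels = 1 + len(config.radii_px)
    fig, axes = plt.subplots(1, n_panels, figsize=(4 * n_panels, 4))
    axes = np.atleast_1d(axes)
    axes[0].imshow(compensated.pixels, cmap="gray", vmin=0, vmax=1)
    axes[0].set_title(f"{row.eye_id} compensated")
    for ax, radius in zip(axes[1:], config.radii_px):
        mask = segment_flow_deficits(compensated, config.threshold_params(radius))
        ax.imshow(mask.pixels, cmap="gray")
        ax.set_title(f"deficits r={radius}px")
    for ax in axes:
        ax.axis("off")
    fig.tight_layout()
    fig.savefig(out_dir / f"qc_{row.eye_id}.png", dpi=120)
    plt.close(fig)


def run_pipeline(
    manifest: CohortManifest,
    config: PipelineConfig | None = None,
    out_dir: str | Path | None = None,
) -> PipelineResult:
    """Run the whole analysis over a cohort manifest.

    Writes, when ``out_dir`` is given: ``per_eye_metrics.csv``,
    ``group_metrics_r<radius>.csv`` (per-eye-averaged metrics) and
    ``group_corners_r<radius>.csv`` (per-quadrant FD%) per radius, an
    MNV-subgroup FD% comparison when both MNV strata are populated, QC
    panels if enabled, and ``run_log.txt`` recording every parameter.
    """
    config = config or PipelineConfig()
    logging.basicConfig(level=config.log_level)
    records: list[EyeRecord] = []
    failed: list[str] = []
    for row in manifest:
        try:
            records.append(process_eye(row, config))
        except Exception as exc:  # noqa: BLE001 - per-eye isolation is the contract
            log.error("eye %s failed and was skipped: %s", row.eye_id, exc)
            failed.append(row.eye_id)
    if not records:
        raise RuntimeError("no eyes survived processing; aborting")

    per_eye = _per_eye_frame(records, config.radii_px)
    tables: dict[str, pd.DataFrame] = {}
    have_two_groups = all(
        sum(r.group == g for r in records) >= 2 for g in ("angioid_streaks", "control")
    )
    if have_two_groups:
        for radius in config.radii_px:
            rows = summarize_groups(records, radius, test=config.group_test)
            frame = comparisons_to_frame(rows)
            is_corner = frame["metric"].str.contains("quadrant")
            tables[f"metrics_r{radius}"] = frame[~is_corner].reset_index(drop=True)
            tables[f"corners_r{radius}"] = frame[is_corner].reset_index(drop=True)
    # MNV subgroup contrast: FD% among diseased eyes with vs without MNV
    mnv = [r for r in records if r.mnv_status == "mnv"]
    no_mnv = [r for r in records if r.mnv_status == "no_mnv"]
    if len(mnv) >= 2 and len(no_mnv) >= 2:
        from .group_stats import mann_whitney_u

        mnv_rows = []
        for radius in config.radii_px:
            a = np.array([r.averages[radius].fd_percent for r in mnv])
            b = np.array([r.averages[radius].fd_percent for r in no_mnv])
            res = mann_whitney_u(a, b)
            mnv_rows.append(
                {
                    "metric": "mean FD%",
                    "radius_px": radius,
                    "mnv_mean": a.mean(),
                    "mnv_sd": a.std(ddof=1),
                    "no_mnv_mean": b.mean(),
                    "no_mnv_sd": b.std(ddof=1),
                    "n_mnv": a.size,
                    "n_no_mnv": b.size,
                    "statistic": res.statistic,
                    "p_value": res.p_value,
                }
            )
        tables["mnv_fd_percent"] = pd.DataFrame(mnv_rows)

    out_path = None
    if out_dir is not None:
        out_path = Path(out_dir)
        out_path.mkdir(parents=True, exist_ok=True)
        per_eye.to_csv(out_path / "per_eye_metrics.csv", index=False)
        for name, frame in tables.items():
            prefix = "group_" if name.startswith(("metrics", "corners")) else ""
            frame.to_csv(out_path / f"{prefix}{name}.csv", index=False)
        if config.qc_panels:
            ok = {r.eye_id for r in records}
            for row in manifest:
                if row.eye_id in ok:
                    _qc_panel(row, config, out_path)
        _write_log(out_path, manifest, config, records, failed)
    return PipelineResult(
        per_eye=per_eye, records=records, tables=tables, failed_eyes=failed, out_dir=out_path
    )


def _write_log(out_path, manifest, config, records, failed) -> None:
    lines = [
        f"ccflow version {__version__}",
        f"eyes in manifest: {len(manifest)}",
        f"eyes processed: {len(records)}",
        f"eyes failed/skipped: {failed or 'none'}",
        "configuration:",
    ]
    for key, value in asdict(config).items():
        lines.append(f"  {key}: {value}")
    (out_path / "run_log.txt").write_text("\n".join(lines) + "\n", encoding="utf-8")
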