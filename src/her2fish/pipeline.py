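"""End-to-end orchestration: detect, crop, count, score, report, evaluate.

``run_image`` wires the two-stage analysis together: the nucleus detector
grades every nucleus by appearance (first read), the signal detector counts
HER2/CEN17 spots in a crop around each nucleus (second read), and the
scoring rules turn both reads into an image-wide grade whose final call
requires the reads to agree.  Each per-image :class:`Report` carries the
full per-nucleus table so that every aggregate can be recomputed from it.

``evaluate_table3`` re-derives the grade calls for the packaged 57-image
validation table from its printed ratios and compares the pipeline's
consensus against the pathologist majority.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from PIL import Image, ImageDraw

from .annotations import BoundingBox, NucleusClass, SignalClass, load_image
from .config import PipelineConfig
from .detection import (
    NucleusDetection,
    SignalDetection,
    _nms,
    assign_signals,
    detect_nuclei,
    detect_signals,
)
from .annotations import crop as crop_image
from .scoring import (
    ImageCall,
    ImageResult,
    NucleusRecord,
    SignalCounts,
    consensus,
    nd_image_call,
    score_image,
    sd_image_call,
)

__all__ = [
    "Report",
    "run_image",
    "run_dataset",
    "render_overlay",
    "report_from_records",
    "Table3Report",
    "evaluate_table3",
    "table3_fixture_path",
]

logger = logging.getLogger("her2fish")

_NUCLEUS_COLORS = {
    NucleusClass.NORMAL: (255, 255, 255),
    NucleusClass.LOW: (255, 255, 0),
    NucleusClass.HIGH: (255, 0, 255),
    NucleusClass.UNCERTAIN: (160, 160, 160),
    NucleusClass.ARTIFACT: (90, 90, 90),
}
# HER2 light blue, HER2 cluster dark blue, CEN17 red
_SIGNAL_COLORS = {
    SignalClass.HER2: (135, 206, 250),
    SignalClass.HER2_CLUSTER: (0, 0, 139),
    SignalClass.CEN17: (255, 0, 0),
}


@dataclass(frozen=True)
class Report:
    """Per-image record of both reads plus everything needed to re-derive them."""

    image_id: str
    result: ImageResult
    signals: tuple[SignalDetection, ...]  # image coordinates, deduplicated

    def to_tsv(self) -> str:
        """Machine-readable block: aggregates as comments, one row per nucleus."""
        r = self.result
        buf = io.StringIO()
        mean = "NA" if r.mean_ratio is None else f"{r.mean_ratio:.2f}"
        buf.write(f"# image\t{self.image_id}\n")
        buf.write(f"# ratio1\t{r.ratio1:.2f}\n")
        buf.write(f"# ratio2\t{r.ratio2:.2f}\n")
        buf.write(f"# mean_her2_cen17\t{mean}\n")
        buf.write(f"# nd_call\t{r.nd_call}\n")
        buf.write(f"# sd_call\t{r.sd_call}\n")
        buf.write(f"# final_call\t{r.final_call}\n")
        for warning in r.warnings:
            buf.write(f"# warning\t{warning}\n")
        buf.write(
            "nucleus_id\tx_min\ty_min\tx_max\ty_max\tnd_class\t"
            "n_her2\tn_cen17\tn_cluster\tratio\tsd_class\tconcordant\n"
        )
        for rec in r.nuclei:
            b = rec.box if isinstance(rec.box, BoundingBox) else BoundingBox(0, 0, 1, 1)
            ratio = "NA" if rec.ratio is None else f"{rec.ratio:.2f}"
            buf.write(
                f"{rec.nucleus_id}\t{b.x_min}\t{b.y_min}\t{b.x_max}\t{b.y_max}\t"
                f"{rec.nd_class}\t{rec.counts.n_her2}\t{rec.counts.n_cen17}\t"
                f"{rec.counts.n_cluster}\t{ratio}\t{rec.sd_class}\t"
                f"{'yes' if rec.concordant else 'no'}\n"
            )
        return buf.getvalue()

    def to_text(self) -> str:
        """Human-readable summary of the double reading."""
        r = self.result
        lines = [
            f"FISH image report: {self.image_id}",
            f"  nuclei detected: {len(r.nuclei)}",
            f"  ratio-1 (low-grade fraction):  {r.ratio1:.2f}",
            f"  ratio-2 (high-grade fraction): {r.ratio2:.2f}",
            "  mean HER2/CEN17 ratio: "
            + ("undefined" if r.mean_ratio is None else f"{r.mean_ratio:.2f}"),
            f"  nucleus-detector call: {r.nd_call}",
            f"  signal-detector call:  {r.sd_call}",
            f"  final call: {r.final_call}",
        ]
        disagreements = [rec for rec in r.nuclei if not rec.concordant]
        lines.append(f"  nuclei with discordant reads: {len(disagreements)}")
        for rec in disagreements:
            lines.append(
                f"    nucleus {rec.nucleus_id}: appearance={rec.nd_class}, "
                f"counts={rec.sd_class} "
                f"(HER2={rec.counts.n_her2}, CEN17={rec.counts.n_cen17}, "
                f"clusters={rec.counts.n_cluster})"
            )
        for warning in r.warnings:
            lines.append(f"  warning: {warning}")
        return "\n".join(lines) + "\n"


def _dedup_signals(signals: Sequence[SignalDetection], nms_iou: float) -> list[SignalDetection]:
    """Merge duplicate detections of one physical spot seen from several crops."""
    out: list[SignalDetection] = []
    for cls in SignalClass:
        out.extend(_nms([s for s in signals if s.signal_class is cls], nms_iou))
    out.sort(key=lambda s: (s.box, s.signal_class.value))
    return out


def run_image(
    image: np.ndarray,
    config: PipelineConfig | None = None,
    image_id: str = "image",
) -> tuple[ImageResult, Report]:
    """Run the full two-stage analysis on one RGB FISH image."""
    config = config or PipelineConfig()
    nuclei = detect_nuclei(image, config.detector)
    logger.info("%s: %d nuclei detected", image_id, len(nuclei))

    pooled: list[SignalDetection] = []
    for det in nuclei:
        sub, (ox, oy) = crop_image(image, det.box, config.crop_margin)
        pooled.extend(s.shift(ox, oy) for s in detect_signals(sub, config.detector))
    signals = _dedup_signals(pooled, config.detector.nms_iou)
    counts, _unassigned = assign_signals(nuclei, signals)

    records = [
        NucleusRecord.from_counts(
            i, counts[i],
            nd_class=det.appearance_class,
            thresholds=config.scoring,
            box=det.box,
            confidence=det.confidence,
        )
        for i, det in enumerate(nuclei)
    ]
    result = score_image(records, config.scoring)
    if not nuclei:
        logger.warning("%s: no nuclei detected", image_id)
    return result, Report(image_id=image_id, result=result, signals=tuple(signals))


def report_from_records(
    image_id: str,
    records: Sequence[NucleusRecord],
    config: PipelineConfig | None = None,
) -> Report:
    """Rebuild a report (aggregates included) from a per-nucleus table."""
    config = config or PipelineConfig()
    return Report(
        image_id=image_id,
        result=score_image(records, config.scoring),
        signals=(),
    )


def render_overlay(
    image: np.ndarray,
    report: Report | ImageResult,
    path: str | Path,
) -> Path:
    """Write a PNG with nucleus boxes colored by class and signal boxes in the
    HER2 light blue / cluster dark blue / CEN17 red scheme."""
    result = report.result if isinstance(report, Report) else report
    signals = report.signals if isinstance(report, Report) else ()
    im = Image.fromarray(np.asarray(image, dtype=np.uint8), mode="RGB")
    draw = ImageDraw.Draw(im)
    for rec in result.nuclei:
        if isinstance(rec.box, BoundingBox):
            b = rec.box
            draw.rectangle(
                [b.x_min, b.y_min, b.x_max - 1, b.y_max - 1],
                outline=_NUCLEUS_COLORS[rec.nd_class], width=2,
            )
    for sig in signals:
        b = sig.box
        draw.rectangle(
            [b.x_min, b.y_min, b.x_max - 1, b.y_max - 1],
            outline=_SIGNAL_COLORS[sig.signal_class], width=1,
        )
    path = Path(path)
    im.save(path)
    return path


def run_dataset(
    manifest: str | Path,
    config: PipelineConfig | None = None,
    out_dir: str | Path | None = None,
) -> pd.DataFrame:
    """Analyse every image listed in a manifest TSV; returns the summary table.

    The manifest needs an ``image`` column with paths relative to its own
    directory.  A missing or unreadable image is recorded as a failed row and
    the run continues.  When *out_dir* is given, per-image reports (and
    overlays, if enabled) plus ``summary.tsv`` are written there.
    """
    config = config or PipelineConfig()
    manifest = Path(manifest)
    table = pd.read_csv(manifest, sep="\t")
    if "image" not in table.columns:
        raise ValueError(f"manifest {manifest} lacks an 'image' column")
    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)

    rows = []
    for name in table["image"]:
        image_path = manifest.parent / str(name)
        stem = Path(str(name)).stem
        try:
            image = load_image(image_path)
        except (OSError, FileNotFoundError) as exc:
            logger.error("failed to read %s: %s", image_path, exc)
            rows.append({
                "image": name, "ratio1": np.nan, "ratio2": np.nan,
                "mean_her2_cen17": np.nan, "nd_call": "FAILED",
                "sd_call": "FAILED", "final_call": "FAILED", "status": "failed",
            })
            continue
        result, report = run_image(image, config, image_id=stem)
        if out_path is not None:
            if config.report.tsv:
                (out_path / f"{stem}.report.tsv").write_text(report.to_tsv())
            if config.report.text:
                (out_path / f"{stem}.report.txt").write_text(report.to_text())
            if config.report.overlays:
                render_overlay(image, report, out_path / f"{stem}.overlay.png")
        rows.append({
            "image": name,
            "ratio1": round(result.ratio1, 2),
            "ratio2": round(result.ratio2, 2),
            "mean_her2_cen17": np.nan if result.mean_ratio is None else round(result.mean_ratio, 2),
            "nd_call": str(result.nd_call),
            "sd_call": str(result.sd_call),
            "final_call": str(result.final_call),
            "status": "ok",
        })
    summary = pd.DataFrame(rows)
    if out_path is not None:
        summary.to_csv(out_path / "summary.tsv", sep="\t", index=False)
    return summary


# ---------------------------------------------------------------------------
# Printed validation-table evaluation
# ---------------------------------------------------------------------------

def table3_fixture_path() -> Path:
    """Path of the packaged 57-image validation table."""
    return Path(resources.files("her2fish.data") / "table3.tsv")


@dataclass(frozen=True)
class Table3Report:
    """Concordance of recomputed grade calls with the printed validation table."""

    frame: pd.DataFrame
    n_images: int
    n_nd_reproduced: int        # recomputed ND call equals the printed one
    n_sd_reproduced: int        # recomputed SD call equals the printed one
    n_discordant: int           # final call undefined (reads disagree)
    n_concordant_correct: int   # final call defined and equal to pathologist majority
    percent_concordant_correct: float

    def to_text(self) -> str:
        return (
            f"Validation-table concordance ({self.n_images} images)\n"
            f"  nucleus-detector calls reproduced: {self.n_nd_reproduced}/{self.n_images}\n"
            f"  signal-detector calls reproduced:  {self.n_sd_reproduced}/{self.n_images}\n"
            f"  discordant images (reads disagree): {self.n_discordant}\n"
            f"  concordant and matching the pathologist majority: "
            f"{self.n_concordant_correct}/{self.n_images} "
            f"({self.percent_concordant_correct:.1f}%)\n"
        )


def _majority(labels: Sequence[str]) -> str:
    values, counts = np.unique(list(labels), return_counts=True)
    order = np.lexsort((values, -counts))
    return str(values[order[0]])


def evaluate_table3(
    fixture: str | Path | None = None,
    thresholds=None,
) -> Table3Report:
    """Recompute both grade calls per validation image and check concordance.

    For every row, the ND call is re-derived from the printed (ratio-1,
    ratio-2) pair and the SD call from the printed mean HER2/CEN17 ratio;
    both are compared against the printed calls.  The final consensus call is
    then compared to the majority grade of the three pathologists.
    """
    from .scoring import DEFAULT_THRESHOLDS

    thresholds = thresholds or DEFAULT_THRESHOLDS
    path = Path(fixture) if fixture is not None else table3_fixture_path()
    frame = pd.read_csv(path, sep="\t")
    required = {
        "image", "ratio1", "ratio2", "her2_cen17", "nd_call", "sd_call",
        "pathologist1", "pathologist2", "pathologist3",
    }
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"fixture {path} lacks columns {sorted(missing)}")

    nd_calls, sd_calls, finals, majorities = [], [], [], []
    for row in frame.itertuples():
        nd = nd_image_call(float(row.ratio1), float(row.ratio2), thresholds)
        sd = sd_image_call(float(row.her2_cen17), thresholds)
        nd_calls.append(str(nd))
        sd_calls.append(str(sd))
        finals.append(str(consensus(nd, sd)))
        majorities.append(_majority([row.pathologist1, row.pathologist2, row.pathologist3]))

    frame = frame.assign(
        nd_recomputed=nd_calls,
        sd_recomputed=sd_calls,
        final_call=finals,
        pathologist_majority=majorities,
    )
    frame["nd_reproduced"] = frame["nd_recomputed"] == frame["nd_call"]
    frame["sd_reproduced"] = frame["sd_recomputed"] == frame["sd_call"]
    frame["concordant_correct"] = (
        (frame["final_call"] != str(ImageCall.DISCORDANT))
        & (frame["final_call"] == frame["pathologist_majority"])
    )
    n = len(frame)
    n_correct = int(frame["concordant_correct"].sum())
    return Table3Report(
        frame=frame,
        n_images=n,
        n_nd_reproduced=int(frame["nd_reproduced"].sum()),
        n_sd_reproduced=int(frame["sd_reproduced"].sum()),
        n_discordant=int((frame["final_call"] == str(ImageCall.DISCORDANT)).sum()),
        n_concordant_correct=n_correct,
        percent_concordant_correct=100.0 * n_correct / n if n else float("nan"),
    )
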