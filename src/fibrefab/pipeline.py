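"""End-to-end orchestration: volume (real or phantom) to full artifact set.

A single config drives: ingest (TIFF stack or inline phantom spec) →
orientation field → directional statistics (axis summary; sagittal,
frontal and transverse rose histograms in frequency and sum-magnitude
weightings; anisotropy summaries overall and per dominant axis; optional
region contrast) → morphometry → export (field CSV, histogram CSV/JSON,
summary JSON, manifest with checksums).  Runs are wholly deterministic
given the seed: repeating a run yields byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Optional

import numpy as np

from . import __version__
from ._axes import validate_axis_map
from .directional_stats import (
    PLANES,
    dominant_axis_fractions,
    region_contrast,
    rose_histogram,
    summarize_anisotropy,
)
from .fabric import sample_directions
from .morphometry import tissue_metrics
from .orientation_field import (
    WindowSpec,
    map_orientation_field,
    window_region_labels,
)
from .phantoms import DiscPhantomSpec, PhantomSpec, generate_phantom, make_disc_phantom
from .volume_io import export_field_csv, read_volume_stack

__all__ = ["RunConfig", "RunManifest", "PipelineStageError", "run_pipeline"]

log = logging.getLogger("fibrefab.pipeline")


class PipelineStageError(RuntimeError):
    """A stage failed; carries the stage name and the partial manifest."""

    def __init__(self, stage: str, cause: BaseException, partial_manifest):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause
        self.partial_manifest = partial_manifest


@dataclass
class RunConfig:
    """Configuration of one analysis run (flat YAML/JSON mirror)."""

    out_dir: str
    phantom: Optional[object] = None          # PhantomSpec | DiscPhantomSpec
    input_path: Optional[str] = None
    spacing_um: Optional[float] = None
    axis_map: tuple = ("X", "Y", "Z")
    legend: Optional[dict] = None
    tissue_label: Optional[int] = None
    window: WindowSpec = dc_field(default_factory=WindowSpec)
    n_directions: int = 128
    line_spacing_vox: float = 2.0
    n_bins: int = 18
    contrast_regions: Optional[tuple] = None  # (region_a_label, region_b_label)
    seed: Optional[int] = None

    def __post_init__(self):
        if (self.phantom is None) == (self.input_path is None):
            raise ValueError("exactly one of phantom or input_path is required")
        if self.input_path is not None and self.spacing_um is None:
            raise ValueError("spacing_um is required with input_path")
        self.axis_map = validate_axis_map(self.axis_map)
        if self.seed is not None and self.phantom is not None:
            self.phantom = dataclasses.replace(self.phantom, seed=int(self.seed))

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw)
        phantom = raw.pop("phantom", None)
        if phantom is not None and not isinstance(
            phantom, (PhantomSpec, DiscPhantomSpec)
        ):
            p = dict(phantom)
            p["shape"] = tuple(p["shape"])
            if p.pop("kind", "disc") == "disc" and "rim_width_fraction" in p:
                phantom = DiscPhantomSpec(**p)
            else:
                p2 = dict(phantom)
                p2["shape"] = tuple(p2["shape"])
                phantom = PhantomSpec(**p2)
        window = raw.pop("window", None)
        if window is not None and not isinstance(window, WindowSpec):
            window = WindowSpec(**window)
        kwargs = dict(raw)
        if phantom is not None:
            kwargs["phantom"] = phantom
        if window is not None:
            kwargs["window"] = window
        if "contrast_regions" in kwargs and kwargs["contrast_regions"] is not None:
            kwargs["contrast_regions"] = tuple(kwargs["contrast_regions"])
        return cls(**kwargs)

    def to_dict(self) -> dict:
        out = {
            "out_dir": str(self.out_dir),
            "input_path": self.input_path,
            "spacing_um": self.spacing_um,
            "axis_map": list(self.axis_map),
            "legend": self.legend,
            "tissue_label": self.tissue_label,
            "window": dataclasses.asdict(self.window),
            "n_directions": self.n_directions,
            "line_spacing_vox": self.line_spacing_vox,
            "n_bins": self.n_bins,
            "contrast_regions": (
                list(self.contrast_regions) if self.contrast_regions else None
            ),
            "seed": self.seed,
        }
        if self.phantom is not None:
            out["phantom"] = dataclasses.asdict(self.phantom)
            out["phantom"]["shape"] = list(self.phantom.shape)
        return out


@dataclass
class RunManifest:
    """Config echo, package version, stage counts and output checksums."""

    config: dict
    version: str
    counts: dict
    outputs: dict  # file name -> sha256 hex digest
    out_dir: str


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_json(path: Path, payload) -> None:
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n",
                    encoding="utf-8")


def _summary_dict(s) -> dict:
    return {"mean": s.mean, "median": s.median, "sd": s.sd, "n": s.n}


def run_pipeline(config: RunConfig) -> RunManifest:
    """Execute the full analysis described by ``config``.

    Any stage error aborts with a :class:`PipelineStageError` naming the
    stage and carrying a partial manifest of the outputs completed so far.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    outputs: dict = {}
    counts: dict = {}
    manifest = RunManifest(config=config.to_dict(), version=__version__,
                           counts=counts, outputs=outputs, out_dir=str(out_dir))

    def fail(stage: str, exc: BaseException):
        raise PipelineStageError(stage, exc, manifest) from exc

    # --- ingest -----------------------------------------------------------
    stage = "ingest"
    try:
        if config.phantom is not None:
            if isinstance(config.phantom, DiscPhantomSpec):
                vol = make_disc_phantom(config.phantom)
            else:
                vol = generate_phantom(config.phantom)
            mask, labels = vol.mask, vol.labels
            spacing, axis_map = vol.spacing_um, vol.axis_map
            if config.tissue_label is not None:
                if labels is None or not np.any(labels == config.tissue_label):
                    raise ValueError(
                        f"tissue label {config.tissue_label} absent from phantom"
                    )
                mask = mask & (labels == config.tissue_label)
        else:
            loaded = read_volume_stack(config.input_path, config.spacing_um,
                                       config.axis_map, legend=config.legend)
            spacing, axis_map = loaded.spacing_um, loaded.axis_map
            if hasattr(loaded, "labels"):
                labels = loaded.labels
                if config.tissue_label is None:
                    raise ValueError("tissue_label is required for a label map")
                if not np.any(labels == config.tissue_label):
                    raise ValueError(
                        f"tissue label {config.tissue_label} absent from volume"
                    )
                mask = labels == config.tissue_label
            else:
                labels = None
                mask = loaded.data > 0
        counts["material_voxels"] = int(np.count_nonzero(mask))
        log.info("ingest: shape=%s material_voxels=%d", mask.shape,
                 counts["material_voxels"])
    except PipelineStageError:
        raise
    except Exception as exc:
        fail(stage, exc)

    # --- orientation field ------------------------------------------------
    stage = "orientation_field"
    try:
        directions = sample_directions(config.n_directions)
        field = map_orientation_field(
            mask, spacing, axis_map, config.window, directions,
            config.line_spacing_vox,
        )
        counts["windows_total"] = field.n_windows
        counts["windows_retained"] = field.vector_count
        counts["windows_skipped"] = dict(field.skipped)
        counts["vector_count"] = field.vector_count
        log.info("orientation_field: retained=%d skipped=%s",
                 field.vector_count, field.skipped)
        csv_path = out_dir / "field.csv"
        export_field_csv(field, csv_path)
        outputs["field.csv"] = _sha256(csv_path)
    except Exception as exc:
        fail(stage, exc)

    # --- directional statistics -------------------------------------------
    stage = "directional_stats"
    try:
        stats_payload: dict = {}
        if field.vector_count:
            axis_summary = dominant_axis_fractions(field)
            _write_json(out_dir / "axis_summary.json", {
                "counts": dict(zip("XYZ", axis_summary.counts)),
                "fractions": dict(zip("XYZ", axis_summary.fractions)),
                "total": axis_summary.total,
            })
            outputs["axis_summary.json"] = _sha256(out_dir / "axis_summary.json")

            rose_payload = {}
            for plane in PLANES:
                hist = rose_histogram(field, plane, config.n_bins)
                lines = ["bin_start_deg,bin_end_deg,count,sum_magnitude_um"]
                for k in range(len(hist.counts)):
                    lines.append(
                        f"{hist.bin_edges_deg[k]:.9g},"
                        f"{hist.bin_edges_deg[k + 1]:.9g},"
                        f"{hist.counts[k]},{hist.sum_magnitude_um[k]:.9g}"
                    )
                name = f"rose_{plane}.csv"
                (out_dir / name).write_bytes(
                    ("\n".join(lines) + "\n").encode("ascii"))
                outputs[name] = _sha256(out_dir / name)
                rose_payload[plane] = {
                    "bin_edges_deg": list(hist.bin_edges_deg),
                    "counts": list(hist.counts),
                    "sum_magnitude_um": list(hist.sum_magnitude_um),
                    "excluded": hist.excluded,
                }
            _write_json(out_dir / "rose_histograms.json", rose_payload)
            outputs["rose_histograms.json"] = _sha256(
                out_dir / "rose_histograms.json")

            overall = summarize_anisotropy(field)
            per_axis = summarize_anisotropy(field, by_axis=True)
            e1 = field.e1_array()
            mags = field.magnitude_array()
            dom = np.argmax(np.abs(e1), axis=1)
            axis_payload = {}
            for k, name in enumerate("XYZ"):
                sel = mags[dom == k]
                if name in per_axis:
                    axis_payload[name] = {
                        "anisotropy": _summary_dict(per_axis[name]),
                        "magnitude_sum_um": float(sel.sum()),
                        "magnitude_mean_um": float(sel.mean()),
                    }
            stats_payload = {"overall": _summary_dict(overall),
                             "per_axis": axis_payload}
            _write_json(out_dir / "anisotropy.json", stats_payload)
            outputs["anisotropy.json"] = _sha256(out_dir / "anisotropy.json")

            if config.contrast_regions is not None:
                if labels is None:
                    raise ValueError("contrast_regions given but no label map")
                regions = window_region_labels(field, mask, labels)
                a, b = config.contrast_regions
                rc = region_contrast(field, regions, a, b)
                _write_json(out_dir / "region_contrast.json", {
                    "region_a": rc.region_a, "region_b": rc.region_b,
                    "summary_a": _summary_dict(rc.summary_a),
                    "summary_b": _summary_dict(rc.summary_b),
                    "mean_difference": rc.mean_difference,
                })
                outputs["region_contrast.json"] = _sha256(
                    out_dir / "region_contrast.json")
        log.info("directional_stats: planes=%d", len(PLANES))
    except Exception as exc:
        fail(stage, exc)

    # --- morphometry ------------------------------------------------------
    stage = "morphometry"
    try:
        report = tissue_metrics(mask.astype(np.uint8), 1, spacing,
                                directions=directions,
                                line_spacing_vox=config.line_spacing_vox)
        _write_json(out_dir / "morphometry.json", {
            "volume_mm3": report.volume_mm3,
            "extent_mm": report.extent_mm,
            "thickness_um": report.thickness_um,
            "separation_um": report.separation_um,
            "volume_fraction": report.volume_fraction,
            "global_anisotropy": report.global_anisotropy,
            "primary_axis": report.primary_axis,
            "fabric_eigenvalues_um": list(report.fabric_eigenvalues_um),
        })
        outputs["morphometry.json"] = _sha256(out_dir / "morphometry.json")
        log.info("morphometry: volume=%.4g mm3 anisotropy=%.3f",
                 report.volume_mm3, report.global_anisotropy)
    except Exception as exc:
        fail(stage, exc)

    # --- manifest ---------------------------------------------------------
    stage = "export"
    try:
        _write_json(out_dir / "manifest.json", {
            "config": manifest.config, "version": manifest.version,
            "counts": counts, "outputs": outputs,
        })
    except Exception as exc:
        fail(stage, exc)
    return manifest
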