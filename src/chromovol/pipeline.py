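"""Seeded, logged orchestration: phantom -> segment -> measure -> account.

A run is described by a serializable :class:`RunConfig`; every stage's
intermediates are persisted in the output directory and a manifest
(config + package version + seed) is written alongside a machine-readable
``report.json``. Re-running the same manifest reproduces the report
byte-for-byte (no timestamps enter the report).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from chromovol import __version__, accounting, morphometry, phantom, proteomics, segmentation
from chromovol.segmentation import SegmentationParams
from chromovol.volume_io import read_stack, write_stack, write_table

log = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; partial outputs are left on disk."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage


@dataclass
class RunConfig:
    """One reproducible run of the analysis pipeline.

    ``stage`` picks the canonical phantom conditions (prophase,
    metaphase, or the clumped periphery-loss analogue) unless an explicit
    ``input_stack`` path or phantom override is given. Per-stage seeds
    derive deterministically from the master seed.
    """

    stage: str = "metaphase"
    seed: int = 0
    input_stack: str | None = None
    phantom_overrides: dict = field(default_factory=dict)
    segmentation: dict = field(default_factory=dict)
    smoothing_level: int = 6
    genome_total_mb: float = 12344.0
    shell_thickness_nm: tuple[float, float] = (143.0, 160.0)
    proteomics_n_proteins: int = 0   # 0 = skip the proteomics stage
    proteomics_n_experiments: int = 24
    proteomics_threshold: float = 0.8

    @staticmethod
    def from_yaml(path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if "shell_thickness_nm" in data:
            data["shell_thickness_nm"] = tuple(data["shell_thickness_nm"])
        return RunConfig(**data)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["shell_thickness_nm"] = list(self.shell_thickness_nm)
        return d


_SPEC_FACTORY = {
    "prophase": phantom.prophase_spec,
    "metaphase": phantom.metaphase_spec,
    "ki67_depleted": phantom.ki67_depleted_spec,
}


def _stage_seed(master: int, stage_name: str) -> int:
    # deterministic per-stage sub-seed, kept below 2**31
    # (zlib.crc32 is stable across processes, unlike hash())
    import zlib

    ss = np.random.SeedSequence([int(master), zlib.crc32(stage_name.encode())])
    return int(ss.generate_state(1)[0] % (2**31))


def run(config: RunConfig, outdir: str | Path) -> dict:
    """Execute the configured stages and return the run report dict.

    Persists: phantom volume + truth labels (or the input stack), the
    segmented label volume, the morphometry CSV, ``report.json`` and
    ``manifest.json``. Any stage error raises :class:`StageError` naming
    the stage, with earlier outputs already on disk.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if config.stage not in _SPEC_FACTORY:
        raise ValueError(f"unknown stage '{config.stage}'")

    manifest = {"config": config.to_dict(), "version": __version__, "seed": config.seed}
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))

    report: dict = {"stage": config.stage, "seed": config.seed}
    truth = None

    # --- input volume -------------------------------------------------------
    stage_name = "phantom" if config.input_stack is None else "load"
    try:
        if config.input_stack is None:
            spec = _SPEC_FACTORY[config.stage](
                seed=_stage_seed(config.seed, "phantom"), **config.phantom_overrides
            )
            grid, truth = phantom.generate_phantom(spec)
            write_stack(grid, outdir / "volume.tif")
            write_stack(truth.labels, outdir / "truth_labels.tif")
            report["phantom"] = {
                "n_objects_truth": int(truth.labels.n_labels),
                "truth_total_volume_um3": float(truth.volume_um3.sum()),
            }
        else:
            grid = read_stack(config.input_stack)
    except Exception as exc:  # noqa: BLE001 - stage boundary
        raise StageError(stage_name, exc) from exc

    # --- segmentation ---------------------------------------------------------
    try:
        params = SegmentationParams(**config.segmentation)
        labels, used_threshold = segmentation.segment(grid, params)
        write_stack(labels, outdir / "labels.tif")
        report["segmentation"] = {
            "threshold": used_threshold,
            "h": params.h,
            "n_objects": int(labels.n_labels),
        }
    except Exception as exc:  # noqa: BLE001
        raise StageError("segmentation", exc) from exc

    # --- morphometry ------------------------------------------------------------
    try:
        env = truth.envelope_mask if truth is not None else None
        records = morphometry.measure_all(
            labels, grid, envelope_mask=env, smoothing_level=config.smoothing_level
        )
        write_table(records, outdir / "morphometry.csv")
        total_volume = float(sum(r.volume_um3 for r in records))
        total_surface = float(sum(r.surface_um2 for r in records))
        report["morphometry"] = {
            "n_objects": len(records),
            "total_volume_um3": total_volume,
            "total_surface_um2": total_surface,
            "mean_diameter_um": float(np.mean([r.diameter_um for r in records])) if records else 0.0,
        }
    except Exception as exc:  # noqa: BLE001
        raise StageError("morphometry", exc) from exc

    # --- accounting ------------------------------------------------------------
    try:
        acct: dict = {}
        if total_volume > 0:
            acct["packing_density_mb_per_um3"] = accounting.packing_density(
                config.genome_total_mb, total_volume
            )
        if records:
            mean_d = report["morphometry"]["mean_diameter_um"]
            acct["periphery_fraction_band"] = {
                f"{int(t)}nm": accounting.periphery_fraction(mean_d, t)
                for t in config.shell_thickness_nm
                if t < mean_d / 2 * 1000.0
            }
        report["accounting"] = acct
    except Exception as exc:  # noqa: BLE001
        raise StageError("accounting", exc) from exc

    # --- proteomics (optional) ---------------------------------------------------
    if config.proteomics_n_proteins > 0:
        try:
            table = phantom.generate_intensity_table(
                n_proteins=config.proteomics_n_proteins,
                n_experiments=config.proteomics_n_experiments,
                seed=_stage_seed(config.seed, "proteomics"),
            )
            graph = proteomics.correlation_network(table, edge_threshold=config.proteomics_threshold)
            cluster_df = proteomics.cluster_annotation_report(graph, table)
            cluster_df.to_csv(outdir / "proteomics_clusters.csv", index=False)
            report["proteomics"] = {
                "group_mass_pct": proteomics.mass_fraction_by_group(table).round(6).to_dict(),
                "n_clusters": int((~cluster_df["singleton"]).sum()),
            }
        except Exception as exc:  # noqa: BLE001
            raise StageError("proteomics", exc) from exc

    (outdir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report


def compare_stages(prophase_report: dict, metaphase_report: dict) -> dict:
    """Cross-stage accounting: volume excess and surface reduction.

    Percent differences are taken on the larger base, matching the
    convention of :func:`chromovol.accounting.percent_difference`.
    """
    pv = prophase_report["morphometry"]["total_volume_um3"]
    ps = prophase_report["morphometry"]["total_surface_um2"]
    mv = metaphase_report["morphometry"]["total_volume_um3"]
    ms = metaphase_report["morphometry"]["total_surface_um2"]
    return {
        "volume_excess_pct": accounting.percent_difference(mv, pv),
        "surface_change_pct": accounting.surface_reduction(ps, ms),
        "prophase_total_volume_um3": pv,
        "metaphase_total_volume_um3": mv,
        "prophase_total_surface_um2": ps,
        "metaphase_total_surface_um2": ms,
    }
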