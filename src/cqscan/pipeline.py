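"""Pipeline configuration and the umbrella ``run`` stage driver.

Stage order for the CQ arm: counts -> mask -> CQ -> classify -> calibrate
-> call-locus -> repeat-contrast.  The EVE arm (refine) is independent.
Every run writes a manifest recording the tool version, timestamp, input
checksums, resolved parameters and per-stage row counts.
"""

from __future__ import annotations

import dataclasses
import datetime
import warnings
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from . import io as cio
from .cq import (
    CQConfig,
    MALE_BIASED,
    apply_mask,
    calibrate,
    count_hits,
    count_hits_from_alignments,
    filter_and_classify,
    partition_windows,
)
from .eve import refine
from .locus import call_locus, repeat_contrast
from .simulate import SimulationConfig, write_simulation

__all__ = ["PipelineConfig", "run_pipeline"]

_ALIGNMENT_SUFFIXES = (".bam", ".sam", ".cram")


@dataclasses.dataclass
class PipelineConfig:
    """Everything a full run needs; unknown keys are rejected on load."""

    outdir: str = "cqscan_out"
    seed: int = 0
    log_level: str = "INFO"
    cq: CQConfig = dataclasses.field(default_factory=CQConfig)
    # CQ-arm inputs
    chrom_sizes: str | None = None
    counts: str | None = None
    male: str | None = None
    female: str | None = None
    mask: str | None = None
    # locus stage
    locus_chrom: str | None = None
    max_outlier_distance: int | None = None
    autosomes: list[str] = dataclasses.field(default_factory=list)
    repeats: str | None = None
    repeat_labels: list[str] = dataclasses.field(default_factory=list)
    # EVE arm
    hits: str | None = None
    reciprocal: str | None = None
    taxonomy: str | None = None
    evalue_max: float = 1e-6
    join_gap: int = 100
    # optional simulation to generate the inputs first
    simulate: SimulationConfig | None = None

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown pipeline config keys: {sorted(unknown)}")
        if "cq" in d and isinstance(d["cq"], dict):
            cq_known = {f.name for f in dataclasses.fields(CQConfig)}
            cq_unknown = set(d["cq"]) - cq_known
            if cq_unknown:
                raise ValueError(f"unknown cq config keys: {sorted(cq_unknown)}")
            d["cq"] = CQConfig(**d["cq"])
        if "simulate" in d and isinstance(d["simulate"], dict):
            d["simulate"] = SimulationConfig.from_dict(d["simulate"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _require(path: str | None, what: str) -> Path:
    if path is None:
        raise ValueError(f"pipeline: missing required input {what!r}")
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"pipeline: {what} file not found: {p}")
    return p


def run_cq_stage(
    config: PipelineConfig, outdir: Path, manifest: cio.RunManifest
) -> pd.DataFrame:
    """Windows -> counts -> mask -> classify; writes the window table and
    the male-biased BED."""
    sizes_path = _require(config.chrom_sizes, "chrom_sizes")
    manifest.record_input(sizes_path)
    chrom_sizes = cio.read_chrom_sizes(sizes_path)
    windows = partition_windows(chrom_sizes, config.cq.window_size)
    manifest.stage_rows["windows"] = len(windows)

    if config.mask:
        mask_path = _require(config.mask, "mask")
        manifest.record_input(mask_path)
        masks = cio.read_bed(mask_path)
        windows = apply_mask(windows, masks, config.cq.masked_exclude_fraction)

    if config.counts:
        counts_path = _require(config.counts, "counts")
        manifest.record_input(counts_path)
        windows = count_hits(windows, cio.read_count_table(counts_path))
    else:
        female = _require(config.female, "female alignments")
        male = _require(config.male, "male alignments")
        manifest.record_input(female)
        manifest.record_input(male)
        windows = count_hits_from_alignments(
            windows, female, male,
            window_size=config.cq.window_size, mapq_min=config.cq.mapq_min,
        )

    windows = filter_and_classify(windows, config.cq)
    manifest.stage_rows["classified_windows"] = len(windows)
    windows.to_csv(outdir / "windows.tsv", sep="\t", index=False)

    mb = windows[windows["status"] == MALE_BIASED]
    cio.write_bed(
        mb.assign(name=MALE_BIASED, score=0, strand="."),
        outdir / "male_biased.bed",
    )
    manifest.stage_rows["male_biased_windows"] = len(mb)

    # scatter export: position (window midpoint), CQ, class
    scatter = windows[windows["cq"].notna()][["chrom", "start", "end", "cq", "status"]].copy()
    scatter["position"] = (scatter["start"] + scatter["end"]) // 2
    scatter[["chrom", "position", "cq", "status"]].to_csv(
        outdir / "cq_scatter.tsv", sep="\t", index=False
    )
    return windows


def run_pipeline(config: PipelineConfig) -> cio.RunManifest:
    """Execute every configured stage in order and write the manifest.

    Errors are re-raised with the failing stage's name prefixed.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = cio.RunManifest(
        tool_version=__version__,
        timestamp=datetime.datetime.now(datetime.timezone.utc).isoformat(),
        parameters={
            "seed": config.seed,
            "cq": dataclasses.asdict(config.cq),
            "evalue_max": config.evalue_max,
            "join_gap": config.join_gap,
            "max_outlier_distance": config.max_outlier_distance,
        },
    )

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise type(exc)(f"[{name}] {exc}") from exc

    if config.simulate is not None:
        sim = dataclasses.replace(config.simulate, seed=config.seed)
        paths = stage("simulate", write_simulation, sim, outdir / "sim")
        config = dataclasses.replace(
            config,
            chrom_sizes=str(paths["chrom_sizes"]),
            counts=str(paths["counts"]),
            mask=str(paths["masks"]),
            repeats=str(paths["repeats"]),
            hits=str(paths["hits"]),
            reciprocal=str(paths["reciprocal"]),
            taxonomy=str(paths["taxonomy"]),
        )

    windows = None
    if config.chrom_sizes and (config.counts or (config.male and config.female)):
        windows = stage("cq", run_cq_stage, config, outdir, manifest)

        if config.autosomes:
            report = stage("calibrate", calibrate, windows, config.autosomes)
            cio.write_json(report.to_dict(), outdir / "calibration.json")
            if not report.near_one:
                warnings.warn(
                    "autosomal CQ not near 1; consider cq.normalize", stacklevel=2
                )

        if config.locus_chrom:
            locus = stage(
                "call-locus", call_locus, windows,
                config.locus_chrom, config.max_outlier_distance,
            )
            if locus is None:
                cio.write_json(None, outdir / "locus.json")
            else:
                report = locus.to_dict()
                # 1-based inclusive companion coordinates for human readers
                report["start_1based"] = locus.start + 1
                report["end_1based"] = locus.end
                cio.write_json(report, outdir / "locus.json")
                manifest.stage_rows["locus_male_biased"] = locus.n_male_biased

                if config.repeats:
                    rep_path = _require(config.repeats, "repeats")
                    manifest.record_input(rep_path)
                    annotation = (
                        cio.read_repeatmasker_out(rep_path)
                        if str(rep_path).endswith(".out")
                        else cio.read_bed(rep_path)
                    )
                    sizes = cio.read_chrom_sizes(_require(config.chrom_sizes, "chrom_sizes"))
                    labels = config.repeat_labels or sorted(
                        {cio.split_label(n)[0] for n in annotation["name"]}
                    )
                    contrast = stage(
                        "repeat-contrast", repeat_contrast,
                        locus, annotation, sizes, labels,
                    )
                    contrast.per_label.to_csv(
                        outdir / "repeat_contrast.tsv", sep="\t", index=False
                    )
                    cio.write_json(contrast.to_dict(), outdir / "repeat_contrast.json")

    if config.hits and config.reciprocal:
        hits_path = _require(config.hits, "hits")
        rec_path = _require(config.reciprocal, "reciprocal")
        manifest.record_input(hits_path)
        manifest.record_input(rec_path)
        taxonomy = {}
        if config.taxonomy:
            tax_path = _require(config.taxonomy, "taxonomy")
            manifest.record_input(tax_path)
            taxonomy = cio.read_taxonomy(tax_path)
        integrations, summary = stage(
            "eve-refine", refine,
            cio.read_hit_table(hits_path), cio.read_hit_table(rec_path), taxonomy,
            evalue_max=config.evalue_max, join_gap=config.join_gap,
        )
        rows = [
            {
                "chrom": c.chrom, "start": c.start, "end": c.end,
                "length_bp": c.length_bp, "status": c.status,
                "family": c.assigned_family,
                "best_species": c.best_hit.species,
                "best_bitscore": c.best_hit.bitscore,
                "best_evalue": c.best_hit.evalue,
            }
            for c in integrations
        ]
        pd.DataFrame(
            rows, columns=["chrom", "start", "end", "length_bp", "status",
                           "family", "best_species", "best_bitscore", "best_evalue"],
        ).to_csv(outdir / "eves.tsv", sep="\t", index=False)
        bed = pd.DataFrame(
            [(c.chrom, c.start, c.end, c.assigned_family, c.best_hit.bitscore, ".")
             for c in integrations],
            columns=cio.BED_COLUMNS,
        )
        cio.write_bed(bed, outdir / "eves.bed")
        cio.write_json(summary.to_dict(), outdir / "eve_summary.json")
        manifest.stage_rows["eve_integrations"] = len(integrations)

    manifest.write(outdir / "manifest.json")
    return manifest
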