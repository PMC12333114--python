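"""Seeded synthetic inputs for the CQ and EVE analyses.

The generator emulates the statistical structure the downstream stages
assume, at the window level rather than the read level:

* two (or more) autosomes plus one sex chromosome carrying a planted
  hemizygous M-locus interval;
* per-window male/female read counts drawn from independent Poisson
  distributions at configurable depths — the defaults model a balanced
  ~100x/100x male/female short-read design, i.e. a Poisson mean of 100
  reads per sex per 500-bp window;
* inside the M locus the female mean drops to ``female_leak_rate``
  (default 0: perfectly hemizygous, no mismapping leak);
* repeat-mask intervals that suppress window counts in proportion to the
  unmasked fraction (masked reference sequence attracts no alignments);
* a repeat annotation whose per-family merged densities differ inside
  versus outside the planted locus;
* viral homology hit tables with overlapping hits, nearby same-species
  fragments below the 100-bp join distance, and host-protein false
  positives whose best reciprocal hit is eukaryotic.

All randomness flows from ``SimulationConfig.seed`` through named child
streams (layout / counts / viral), so enabling one component never
perturbs the draws of another and identical configs give byte-identical
output files.
"""

from __future__ import annotations

import dataclasses
import zlib
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import io as cio
from .cq import partition_windows, apply_mask
from .io import BED_COLUMNS, HIT_COLUMNS, merge_intervals, merged_coverage

__all__ = [
    "SimulationConfig",
    "GenomeLayout",
    "SimulatedHits",
    "simulate_genome_layout",
    "simulate_window_counts",
    "simulate_viral_hits",
    "write_simulation",
]

#: Virus species available to the hit generator.  Species mapping to
#: ``None`` are deliberately absent from the emitted taxonomy map so that
#: downstream family assignment exercises the "unclassified" path.
VIRUS_POOL: list[tuple[str, str | None]] = [
    ("Aedes aegypti To virus 2", "Metaviridae"),
    ("Aedes aegypti To virus 1", "Metaviridae"),
    ("Imjin chuvirus", "Chuviridae"),
    ("Culex rhabdo-like virus 3", "Rhabdoviridae"),
    ("Anopheles marais virus", "Xinmoviridae"),
    ("Wuhan mosquito virus 1", "Phasmaviridae"),
    ("Phasi Charoen-like virus", "Phenuiviridae"),
    ("Kvarnon virus", None),
    ("Gordis virus", None),
]


def _child_rng(seed: int, stream: str) -> np.random.Generator:
    """Deterministic per-component generator derived from the master seed."""
    return np.random.default_rng([seed & 0x7FFFFFFF, zlib.crc32(stream.encode())])


@dataclasses.dataclass
class SimulationConfig:
    """Seeded description of the synthetic genome and its fixtures.

    Depths are Poisson means in reads per full-width window per sex.
    ``repeat_families`` entries are ``(label, genome_density,
    locus_density)`` with densities as merged-coverage fractions; the
    genome density applies outside the planted locus, the locus density
    inside it.
    """

    chrom_lengths: dict[str, int]
    window_size: int = 500
    female_depth: float = 100.0
    male_depth: float = 100.0
    m_locus: tuple[str, int, int] | None = None
    female_leak_rate: float = 0.0
    male_hemizygous_factor: float = 1.0
    mask_intervals: list[tuple[str, int, int]] = dataclasses.field(default_factory=list)
    repeat_families: list[tuple[str, float, float]] = dataclasses.field(default_factory=list)
    n_viral_hits: int = 0
    n_host_false_positives: int = 0
    viral_gap_range: tuple[int, int] = (20, 99)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.window_size <= 0:
            raise ValueError("window_size must be positive")
        for chrom, length in self.chrom_lengths.items():
            if length <= 0:
                raise ValueError(f"chromosome {chrom!r} has non-positive length")
        for depth in (self.female_depth, self.male_depth,
                      self.female_leak_rate, self.male_hemizygous_factor):
            if depth < 0:
                raise ValueError("depths and rates must be non-negative")
        if self.m_locus is not None:
            chrom, start, end = self.m_locus
            if chrom not in self.chrom_lengths:
                raise ValueError(f"m_locus chromosome {chrom!r} not declared")
            if not (0 <= start < end <= self.chrom_lengths[chrom]):
                raise ValueError(
                    f"m_locus [{start}, {end}) outside chromosome {chrom!r}"
                )
        for chrom, start, end in self.mask_intervals:
            if chrom not in self.chrom_lengths:
                raise ValueError(f"mask interval chromosome {chrom!r} not declared")
            if not (0 <= start < end <= self.chrom_lengths[chrom]):
                raise ValueError(
                    f"mask interval [{start}, {end}) outside chromosome {chrom!r}"
                )
        for label, gdens, ldens in self.repeat_families:
            if not (0 <= gdens <= 1 and 0 <= ldens <= 1):
                raise ValueError(f"repeat densities for {label!r} must be in [0, 1]")
        if self.n_viral_hits < 0 or self.n_host_false_positives < 0:
            raise ValueError("hit counts must be non-negative")

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown simulation config keys: {sorted(unknown)}")
        if "m_locus" in d and d["m_locus"] is not None:
            c, s, e = d["m_locus"]
            d["m_locus"] = (str(c), int(s), int(e))
        d["chrom_lengths"] = {str(k): int(v) for k, v in d["chrom_lengths"].items()}
        if "mask_intervals" in d:
            d["mask_intervals"] = [(str(c), int(s), int(e)) for c, s, e in d["mask_intervals"]]
        if "repeat_families" in d:
            d["repeat_families"] = [(str(n), float(g), float(l)) for n, g, l in d["repeat_families"]]
        if "viral_gap_range" in d:
            lo, hi = d["viral_gap_range"]
            d["viral_gap_range"] = (int(lo), int(hi))
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclasses.dataclass
class GenomeLayout:
    """Resolved synthetic genome: sizes, masks, repeats and ground truth."""

    chrom_sizes: dict[str, int]
    masks: pd.DataFrame  # BED columns
    repeats: pd.DataFrame  # BED columns, name = class/family label
    m_locus: tuple[str, int, int] | None


@dataclasses.dataclass
class SimulatedHits:
    """Viral-hit fixture: forward/reciprocal tables plus ground truth."""

    forward: pd.DataFrame  # extended outfmt 6
    reciprocal: pd.DataFrame  # extended outfmt 6, qseqid = region id
    truth: list[dict]  # one record per planted (joined) integration
    taxonomy: dict[str, tuple[str, str]]  # species -> (family, superkingdom)


# ---------------------------------------------------------------------------
# layout
# ---------------------------------------------------------------------------

def _fill_region(
    rng: np.random.Generator,
    chrom: str,
    region: tuple[int, int],
    label: str,
    density: float,
) -> list[tuple[str, int, int, str]]:
    """Draw repeat intervals inside ``region`` until the merged coverage
    reaches ``density`` of its length.

    Interval lengths are uniform on [200, 1500] bp (typical TE fragment
    scale); the raw, possibly overlapping draws are returned so that
    downstream measurement must merge, and the realised merged density
    overshoots the target by at most one interval length.
    """
    start, end = region
    span = end - start
    target = int(round(density * span))
    if target <= 0 or span <= 0:
        return []
    covered: list[tuple[int, int]] = []
    raw: list[tuple[str, int, int, str]] = []
    coverage = 0
    # cap iterations defensively; coverage growth stalls only at density ~1
    for _ in range(200 * max(1, target // 200)):
        if coverage >= target:
            break
        length = int(rng.integers(200, 1501))
        length = min(length, span)
        s = start + int(rng.integers(0, span - length + 1))
        e = s + length
        raw.append((chrom, s, e, label))
        covered = merge_intervals(covered + [(s, e)])
        coverage = sum(b - a for a, b in covered)
    return raw


def simulate_genome_layout(config: SimulationConfig) -> GenomeLayout:
    """Realise the chromosome sizes, masks, repeat annotation and locus.

    Repeat intervals for each family are drawn independently inside the
    planted locus (at the family's locus density) and outside it (at the
    genome density), so the realised merged densities contrast the way the
    downstream enrichment analysis expects.
    """
    rng = _child_rng(config.seed, "layout")
    rows: list[tuple[str, int, int, str]] = []
    locus = config.m_locus
    for label, gdens, ldens in config.repeat_families:
        for chrom, length in config.chrom_lengths.items():
            if locus is not None and chrom == locus[0]:
                lchrom, lstart, lend = locus
                rows += _fill_region(rng, chrom, (0, lstart), label, gdens)
                rows += _fill_region(rng, chrom, (lstart, lend), label, ldens)
                rows += _fill_region(rng, chrom, (lend, length), label, gdens)
            else:
                rows += _fill_region(rng, chrom, (0, length), label, gdens)
    repeats = pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])
    repeats["score"] = 0
    repeats["strand"] = "."
    repeats = repeats.sort_values(["chrom", "start", "end"], kind="stable").reset_index(drop=True)
    masks = pd.DataFrame(config.mask_intervals, columns=["chrom", "start", "end"])
    masks["name"] = "mask"
    masks["score"] = 0
    masks["strand"] = "."
    return GenomeLayout(
        chrom_sizes=dict(config.chrom_lengths),
        masks=masks[BED_COLUMNS],
        repeats=repeats[BED_COLUMNS],
        m_locus=locus,
    )


# ---------------------------------------------------------------------------
# window counts
# ---------------------------------------------------------------------------

def simulate_window_counts(
    config: SimulationConfig, layout: GenomeLayout
) -> pd.DataFrame:
    """Draw per-window female/male Poisson counts over the layout.

    The Poisson mean of each window scales with (a) its length relative to
    a full window (the final window of a chromosome may be short), (b) its
    unmasked fraction, and (c) for the female mean, the fraction of the
    window inside the M locus, which is served at ``female_leak_rate``
    instead of ``female_depth``.  Fully masked windows therefore draw
    Poisson(0) = 0 in both sexes.
    """
    rng = _child_rng(config.seed, "counts")
    windows = partition_windows(layout.chrom_sizes, config.window_size)
    windows = apply_mask(windows, layout.masks)
    lengths = (windows["end"] - windows["start"]).to_numpy()
    size_frac = lengths / config.window_size
    open_frac = (1.0 - windows["masked_fraction"].to_numpy()) * size_frac

    locus_frac = np.zeros(len(windows))
    if layout.m_locus is not None:
        lchrom, lstart, lend = layout.m_locus
        on = (windows["chrom"] == lchrom).to_numpy()
        ov = (
            np.minimum(windows["end"].to_numpy(), lend)
            - np.maximum(windows["start"].to_numpy(), lstart)
        ).clip(min=0)
        locus_frac = np.where(on, ov / lengths, 0.0)

    lam_f = open_frac * (
        config.female_depth * (1 - locus_frac)
        + config.female_leak_rate * locus_frac
    )
    lam_m = open_frac * config.male_depth * (
        (1 - locus_frac) + config.male_hemizygous_factor * locus_frac
    )
    out = windows[["chrom", "start", "end"]].copy()
    out["female_hits"] = rng.poisson(lam_f)
    out["male_hits"] = rng.poisson(lam_m)
    return out


# ---------------------------------------------------------------------------
# viral hits
# ---------------------------------------------------------------------------

def _blast_row(
    rng: np.random.Generator,
    qseqid: str,
    start: int,
    end: int,
    sseqid: str,
    species: str,
    family: str,
    superkingdom: str,
    bitscore: float,
) -> tuple:
    """One extended outfmt-6 row; genome coordinates are emitted 1-based
    inclusive as BLAST prints them."""
    aln = end - start
    pident = round(float(rng.uniform(35, 95)), 1)
    mismatch = int(aln * (1 - pident / 100) // 3)
    evalue = float(10.0 ** -rng.uniform(10, 60))
    reverse = bool(rng.integers(0, 2))
    qstart, qend = (end, start + 1) if reverse else (start + 1, end)
    return (
        qseqid, sseqid, pident, aln // 3, mismatch, 0,
        qstart, qend, 1, aln // 3,
        evalue, round(bitscore, 1), species, family, superkingdom,
    )


def simulate_viral_hits(
    config: SimulationConfig, layout: GenomeLayout
) -> SimulatedHits:
    """Plant viral integrations and host false positives; emit hit tables.

    Each planted integration is split into 1–3 fragments separated by gaps
    drawn from ``viral_gap_range`` (strictly below the default 100-bp join
    distance, so ground truth lists one joined integration per plant).
    Every fragment carries one spanning forward hit plus 0–2 overlapping
    weaker hits to the same species.  Host false positives are isolated
    forward hits whose best reciprocal hit is a eukaryotic protein.
    Integrations are spaced >= 500 bp apart so distinct plants never join.
    """
    rng = _child_rng(config.seed, "viral")
    forward_rows: list[tuple] = []
    reciprocal_rows: list[tuple] = []
    truth: list[dict] = []
    taxonomy = {
        species: (family, "Viruses")
        for species, family in VIRUS_POOL
        if family is not None
    }

    chroms = list(layout.chrom_sizes)
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}

    def place(total_len: int) -> tuple[str, int] | None:
        for _ in range(100):
            chrom = chroms[int(rng.integers(0, len(chroms)))]
            limit = layout.chrom_sizes[chrom] - total_len
            if limit <= 0:
                continue
            start = int(rng.integers(0, limit))
            pad = 500  # keep plants > join distance apart
            if all(start >= e + pad or start + total_len <= s - pad
                   for s, e in occupied[chrom]):
                occupied[chrom].append((start, start + total_len))
                return chrom, start
        return None

    for i in range(config.n_viral_hits):
        species, family = VIRUS_POOL[int(rng.integers(0, len(VIRUS_POOL)))]
        n_frag = int(rng.integers(1, 4))
        frag_lens = rng.integers(150, 1200, size=n_frag)
        gaps = rng.integers(config.viral_gap_range[0],
                            config.viral_gap_range[1] + 1, size=max(0, n_frag - 1))
        total = int(frag_lens.sum() + gaps.sum())
        spot = place(total)
        if spot is None:
            continue
        chrom, pos = spot
        frag_spans = []
        cursor = pos
        for j in range(n_frag):
            s, e = cursor, cursor + int(frag_lens[j])
            frag_spans.append((s, e))
            cursor = e + (int(gaps[j]) if j < n_frag - 1 else 0)
        protein = f"YP_{900000 + i}"
        for s, e in frag_spans:
            best_bits = float(rng.uniform(120, 400))
            forward_rows.append(_blast_row(
                rng, chrom, s, e, protein, species,
                family or "", "Viruses", best_bits,
            ))
            for _ in range(int(rng.integers(0, 3))):  # overlapping weaker hits
                sub_s = s + int(rng.integers(0, max(1, (e - s) // 2)))
                sub_e = sub_s + max(60, int(rng.integers(60, e - sub_s + 1)))
                sub_e = min(sub_e, e)
                forward_rows.append(_blast_row(
                    rng, chrom, sub_s, sub_e, protein, species,
                    family or "", "Viruses", best_bits - float(rng.uniform(5, 60)),
                ))
            region_id = f"{chrom}:{s}-{e}"
            reciprocal_rows.append(_blast_row(
                rng, region_id, 0, e - s, protein, species,
                family or "", "Viruses", best_bits,
            ))
        truth.append({
            "chrom": chrom,
            "start": frag_spans[0][0],
            "end": frag_spans[-1][1],
            "species": species,
            "family": family or "unclassified",
            "n_fragments": n_frag,
        })

    for i in range(config.n_host_false_positives):
        species, family = VIRUS_POOL[int(rng.integers(0, len(VIRUS_POOL)))]
        length = int(rng.integers(150, 900))
        spot = place(length)
        if spot is None:
            continue
        chrom, s = spot
        e = s + length
        bits = float(rng.uniform(80, 200))
        forward_rows.append(_blast_row(
            rng, chrom, s, e, f"YP_{800000 + i}", species,
            family or "", "Viruses", bits,
        ))
        region_id = f"{chrom}:{s}-{e}"
        # best reciprocal hit is a host protein; a weaker viral hit keeps
        # the best-hit selection honest
        reciprocal_rows.append(_blast_row(
            rng, region_id, 0, length, f"XP_{700000 + i}",
            "Armigeres subalbatus", "", "Eukaryota", bits + float(rng.uniform(20, 80)),
        ))
        reciprocal_rows.append(_blast_row(
            rng, region_id, 0, length, f"YP_{800000 + i}", species,
            family or "", "Viruses", bits - float(rng.uniform(5, 30)),
        ))

    forward = pd.DataFrame(forward_rows, columns=HIT_COLUMNS)
    reciprocal = pd.DataFrame(reciprocal_rows, columns=HIT_COLUMNS)
    truth.sort(key=lambda r: (r["chrom"], r["start"]))
    return SimulatedHits(
        forward=forward, reciprocal=reciprocal, truth=truth, taxonomy=taxonomy
    )


# ---------------------------------------------------------------------------
# file emission
# ---------------------------------------------------------------------------

def write_simulation(config: SimulationConfig, outdir: str | Path) -> dict[str, Path]:
    """Run all three generators and write every fixture file to ``outdir``.

    Emits chrom_sizes.tsv, counts.tsv, masks.bed, repeats.bed, hits.tsv,
    reciprocal.tsv, taxonomy.tsv and truth.json; returns the path map.
    Identical configs (including seed) produce byte-identical files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    layout = simulate_genome_layout(config)
    counts = simulate_window_counts(config, layout)
    hits = simulate_viral_hits(config, layout)

    paths = {name: outdir / fname for name, fname in [
        ("chrom_sizes", "chrom_sizes.tsv"), ("counts", "counts.tsv"),
        ("masks", "masks.bed"), ("repeats", "repeats.bed"),
        ("hits", "hits.tsv"), ("reciprocal", "reciprocal.tsv"),
        ("taxonomy", "taxonomy.tsv"), ("truth", "truth.json"),
    ]}
    with open(paths["chrom_sizes"], "w") as fh:
        for chrom, length in layout.chrom_sizes.items():
            fh.write(f"{chrom}\t{length}\n")
    cio.write_count_table(counts, paths["counts"])
    cio.write_bed(layout.masks, paths["masks"])
    cio.write_bed(layout.repeats, paths["repeats"])
    cio.write_hit_table(hits.forward, paths["hits"])
    cio.write_hit_table(hits.reciprocal, paths["reciprocal"])
    cio.write_taxonomy(hits.taxonomy, paths["taxonomy"])
    cio.write_json(
        {
            "m_locus": list(layout.m_locus) if layout.m_locus else None,
            "integrations": hits.truth,
        },
        paths["truth"],
    )
    return paths
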