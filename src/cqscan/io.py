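"""Shared readers/writers, interval arithmetic and run manifests.

All genomic intervals are 0-based half-open ``[start, end)`` internally and
in every BED/TSV file this package writes.  Human-readable reports convert
to 1-based inclusive at the very edge (see :mod:`cqscan.pipeline`).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "read_chrom_sizes",
    "read_bed",
    "write_bed",
    "merge_intervals",
    "merged_coverage",
    "split_label",
    "label_matches",
    "read_count_table",
    "write_count_table",
    "HIT_COLUMNS",
    "read_hit_table",
    "write_hit_table",
    "read_repeatmasker_out",
    "read_taxonomy",
    "write_json",
    "file_sha256",
    "RunManifest",
]

COUNT_COLUMNS = ["chrom", "start", "end", "female_hits", "male_hits"]

#: Extended BLAST tabular (outfmt 6) dialect: the 12 standard columns plus
#: subject species / family / superkingdom resolved upstream.
HIT_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
    "sspecies", "sfamily", "ssuperkingdom",
]

BED_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


# ---------------------------------------------------------------------------
# chromosome sizes
# ---------------------------------------------------------------------------

def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    """Read a two-column ``name<TAB>length`` table into an ordered dict.

    FASTA-index (``.fai``) files are accepted: only the first two columns
    are used.  Raises ``ValueError`` (with the offending line number) on
    duplicate names, non-integer or non-positive lengths, or an empty file.
    """
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                fields = line.split()
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected at least 2 columns")
            name = fields[0]
            try:
                length = int(fields[1])
            except ValueError:
                raise ValueError(
                    f"{path}:{lineno}: non-integer length {fields[1]!r}"
                ) from None
            if length <= 0:
                raise ValueError(f"{path}:{lineno}: non-positive length for {name!r}")
            if name in sizes:
                raise ValueError(f"{path}:{lineno}: duplicate chromosome {name!r}")
            sizes[name] = length
    if not sizes:
        raise ValueError(f"{path}: empty chromosome sizes file")
    return sizes


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def read_bed(path: str | Path) -> pd.DataFrame:
    """Read BED3/BED6 into a DataFrame with columns chrom..strand.

    Missing BED6 columns are filled with ``"."``/0/``"."``.  Coordinates are
    kept 0-based half-open.  ``start >= end`` raises with the line number.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise ValueError(f"{path}:{lineno}: expected >= 3 BED columns")
            try:
                start, end = int(f[1]), int(f[2])
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from None
            if start >= end:
                raise ValueError(f"{path}:{lineno}: start >= end ({start} >= {end})")
            name = f[3] if len(f) > 3 else "."
            score = f[4] if len(f) > 4 else "0"
            strand = f[5] if len(f) > 5 else "."
            rows.append((f[0], start, end, name, score, strand))
    return pd.DataFrame(rows, columns=BED_COLUMNS)


def write_bed(df: pd.DataFrame, path: str | Path, columns: int = 6) -> None:
    """Write a BED3 or BED6 file from a DataFrame with the BED columns."""
    cols = BED_COLUMNS[:columns]
    out = df.copy()
    for col, default in (("name", "."), ("score", 0), ("strand", ".")):
        if col in cols and col not in out.columns:
            out[col] = default
    out[cols].to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# interval arithmetic (bedtools-merge semantics)
# ---------------------------------------------------------------------------

def merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge intervals that overlap or are book-ended (gap 0).

    This is the transitive closure of the "overlaps or abuts" relation, the
    default behaviour of ``bedtools merge``: ``[100,200)`` and ``[200,300)``
    merge, ``[100,200)`` and ``[201,300)`` do not.  Returns sorted disjoint
    intervals with pairwise gaps >= 1.
    """
    ivs = sorted(intervals)
    if not ivs:
        return []
    merged = [list(ivs[0])]
    for start, end in ivs[1:]:
        if start <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], end)
        else:
            merged.append([start, end])
    return [(s, e) for s, e in merged]


def merged_coverage(
    intervals: Iterable[tuple[int, int]], start: int, end: int
) -> int:
    """Base pairs of ``[start, end)`` covered by the merged intervals."""
    total = 0
    for s, e in merge_intervals(intervals):
        total += max(0, min(e, end) - max(s, start))
    return total


# ---------------------------------------------------------------------------
# repeat labels
# ---------------------------------------------------------------------------

def split_label(name: str) -> tuple[str, str]:
    """Split a ``class/family`` repeat label on the first slash.

    ``"LTR/BEL-Pao"`` -> ``("LTR", "BEL-Pao")``; a bare class yields an
    empty family.
    """
    if "/" in name:
        cls, fam = name.split("/", 1)
        return cls, fam
    return name, ""


def label_matches(name: str, label: str | None) -> bool:
    """True when a repeat annotation label matches a query label.

    A query matches the full ``class/family`` string, the class alone or
    the family alone; ``None`` matches everything.
    """
    if label is None:
        return True
    cls, fam = split_label(name)
    return label in (name, cls, fam)


# ---------------------------------------------------------------------------
# per-window count tables
# ---------------------------------------------------------------------------

def read_count_table(path: str | Path) -> pd.DataFrame:
    """Read the ``chrom start end female_hits male_hits`` TSV."""
    try:
        df = pd.read_csv(
            path, sep="\t",
            dtype={"chrom": str, "start": int, "end": int,
                   "female_hits": int, "male_hits": int},
        )
    except (ValueError, pd.errors.ParserError) as exc:
        raise ValueError(f"{path}: malformed count table: {exc}") from None
    missing = set(COUNT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: count table missing columns {sorted(missing)}")
    if (df["female_hits"] < 0).any() or (df["male_hits"] < 0).any():
        bad = df.index[(df["female_hits"] < 0) | (df["male_hits"] < 0)][0]
        raise ValueError(f"{path}: negative count at line {bad + 2}")
    return df[COUNT_COLUMNS + [c for c in df.columns if c not in COUNT_COLUMNS]]


def write_count_table(df: pd.DataFrame, path: str | Path) -> None:
    df[COUNT_COLUMNS].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# hit tables (extended outfmt 6)
# ---------------------------------------------------------------------------

def read_hit_table(path: str | Path) -> pd.DataFrame:
    """Read an extended outfmt-6 hit table (tab separated, with header).

    Headerless 12- or 15-column files are accepted for interoperability
    with raw BLAST output; missing taxonomy columns yield empty species /
    family and superkingdom ``"unknown"`` with a warning.
    """
    with open(path) as fh:
        first = fh.readline()
    if not first.strip():
        return pd.DataFrame(columns=HIT_COLUMNS)
    has_header = first.split("\t")[0].strip() == "qseqid"
    df = pd.read_csv(path, sep="\t", header=0 if has_header else None)
    if not has_header:
        if len(df.columns) not in (12, 15):
            raise ValueError(
                f"{path}: headerless hit table must have 12 or 15 columns, "
                f"got {len(df.columns)}"
            )
        df.columns = HIT_COLUMNS[: len(df.columns)]
    missing = [c for c in HIT_COLUMNS[:12] if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: hit table missing columns {missing}")
    if "ssuperkingdom" not in df.columns:
        warnings.warn(
            f"{path}: no taxonomy columns; superkingdom set to 'unknown'",
            stacklevel=2,
        )
        df["sspecies"] = df.get("sspecies", "")
        df["sfamily"] = ""
        df["ssuperkingdom"] = "unknown"
    df["sfamily"] = df["sfamily"].fillna("")
    return df[HIT_COLUMNS]


def write_hit_table(df: pd.DataFrame, path: str | Path) -> None:
    df[HIT_COLUMNS].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# RepeatMasker .out
# ---------------------------------------------------------------------------

def read_repeatmasker_out(path: str | Path) -> pd.DataFrame:
    """Parse RepeatMasker ``.out`` into the BED-like repeat DataFrame.

    The whitespace dialect with its 3 header lines is expected; coordinates
    are converted from 1-based inclusive to 0-based half-open and the
    complement strand marker ``C`` is normalised to ``-``.  The ``name``
    column carries the repeat ``class/family`` string.
    """
    rows = []
    with open(path) as fh:
        lines = fh.readlines()
    for lineno, line in enumerate(lines, start=1):
        if lineno <= 3 or not line.strip():
            continue
        f = line.split()
        if len(f) < 11:
            raise ValueError(f"{path}:{lineno}: truncated RepeatMasker row")
        score, chrom = f[0], f[4]
        start = int(f[5]) - 1  # 1-based inclusive -> 0-based half-open
        end = int(f[6])
        strand = "-" if f[8] == "C" else f[8]
        family = f[10]
        rows.append((chrom, start, end, family, score, strand))
    return pd.DataFrame(rows, columns=BED_COLUMNS)


# ---------------------------------------------------------------------------
# taxonomy map
# ---------------------------------------------------------------------------

def read_taxonomy(path: str | Path) -> dict[str, tuple[str, str]]:
    """Read the ``species  family  superkingdom`` TSV into a dict.

    Missing family fields map to an empty string (the species is known but
    unplaced, yielding "unclassified" downstream).
    """
    taxmap: dict[str, tuple[str, str]] = {}
    with open(path) as fh:
        header = fh.readline()
        if header and not header.startswith("species"):
            fh.seek(0)
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            f = line.split("\t")
            species = f[0]
            family = f[1] if len(f) > 1 else ""
            superkingdom = f[2] if len(f) > 2 else "Viruses"
            taxmap[species] = (family, superkingdom)
    return taxmap


def write_taxonomy(taxmap: dict[str, tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("species\tfamily\tsuperkingdom\n")
        for species in sorted(taxmap):
            family, superkingdom = taxmap[species]
            fh.write(f"{species}\t{family}\t{superkingdom}\n")


# ---------------------------------------------------------------------------
# JSON + manifests
# ---------------------------------------------------------------------------

def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclasses.dataclass
class RunManifest:
    """Provenance record emitted next to every pipeline run's outputs."""

    tool_version: str
    timestamp: str
    inputs: dict[str, str] = dataclasses.field(default_factory=dict)  # path -> sha256
    parameters: dict = dataclasses.field(default_factory=dict)
    stage_rows: dict[str, int] = dataclasses.field(default_factory=dict)

    def record_input(self, path: str | Path) -> None:
        self.inputs[str(path)] = file_sha256(path)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def write(self, path: str | Path) -> None:
        write_json(self.to_dict(), path)
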