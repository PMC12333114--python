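"""Endogenous viral element (EVE) annotation refinement.

Consumes precomputed translated-homology hit tables (a forward search of
the genome against viral proteins, and a reciprocal search of extracted
candidate regions against a broad protein database) and refines them into
a set of confirmed viral integrations:

1. drop forward hits above the e-value threshold (default 1e-6);
2. cluster hits that overlap or abut on the genome (transitive closure,
   bedtools-merge semantics);
3. keep the best hit of each cluster (highest bitscore, ties broken by
   e-value, alignment length, subject id);
4. reject candidates whose best reciprocal hit is not viral (host-protein
   false positives) or that have no reciprocal evidence;
5. join confirmed integrations on the same chromosome that derive from
   the same viral species and lie closer than 100 bp apart;
6. assign each joined integration the viral family of its most similar
   virus via a species -> family taxonomy map, and summarise.

The pipeline never runs homology searches itself; absolute genome-scale
EVE counts depend on the search database version and are out of scope.
"""

from __future__ import annotations

import dataclasses
import statistics
import warnings
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .io import read_hit_table

__all__ = [
    "ViralHit",
    "EVECandidate",
    "EVESummary",
    "load_hits",
    "cluster_hits",
    "select_best",
    "reciprocal_filter",
    "join_nearby",
    "assign_family",
    "summarize",
    "refine",
]

CANDIDATE = "candidate"
CONFIRMED = "confirmed"
REJECTED_HOST = "rejected_host"
REJECTED_NO_RECIPROCAL = "rejected_no_reciprocal"

SUPERKINGDOMS = {"Viruses", "Eukaryota", "Bacteria", "Archaea", "unknown"}


@dataclasses.dataclass(frozen=True)
class ViralHit:
    """A homology hit on the genome, normalised to 0-based half-open
    coordinates with ``start < end``; strand records the original
    orientation of the (possibly reversed) raw coordinates."""

    chrom: str
    start: int
    end: int
    strand: str
    subject_id: str
    species: str
    family: str
    superkingdom: str
    evalue: float
    bitscore: float
    aln_length: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty hit interval [{self.start}, {self.end})")
        if self.evalue < 0:
            raise ValueError("evalue must be non-negative")


@dataclasses.dataclass
class EVECandidate:
    """A refined candidate integration: a cluster's merged span, its best
    hit, and its refinement status."""

    chrom: str
    start: int
    end: int
    best_hit: ViralHit
    member_hits: list[ViralHit]
    status: str = CANDIDATE
    assigned_family: str = "unclassified"
    best_reciprocal: ViralHit | None = None

    @property
    def length_bp(self) -> int:
        return self.end - self.start

    @property
    def region_id(self) -> str:
        """Identifier of the extracted region, keying the reciprocal table."""
        return f"{self.chrom}:{self.start}-{self.end}"


@dataclasses.dataclass
class EVESummary:
    """Counts and length statistics over the final integrations."""

    n_total: int
    family_counts: dict[str, int]
    n_unclassified: int
    total_bp: int
    min_bp: int
    max_bp: int
    median_bp: float

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


# ---------------------------------------------------------------------------
# loading
# ---------------------------------------------------------------------------

def _hit_from_row(row) -> ViralHit:
    qstart, qend = int(row.qstart), int(row.qend)
    # BLAST prints 1-based inclusive coordinates, reversed on the minus
    # orientation; normalise to 0-based half-open with start < end.
    if qstart <= qend:
        start, end, strand = qstart - 1, qend, "+"
    else:
        start, end, strand = qend - 1, qstart, "-"
    superkingdom = str(row.ssuperkingdom)
    if superkingdom not in SUPERKINGDOMS:
        superkingdom = "unknown"
    return ViralHit(
        chrom=str(row.qseqid),
        start=start,
        end=end,
        strand=strand,
        subject_id=str(row.sseqid),
        species=str(row.sspecies),
        family=str(row.sfamily) if row.sfamily == row.sfamily else "",
        superkingdom=superkingdom,
        evalue=float(row.evalue),
        bitscore=float(row.bitscore),
        aln_length=int(row.length),
    )


def load_hits(
    table: pd.DataFrame | str | Path, evalue_max: float = 1e-6
) -> list[ViralHit]:
    """Load and normalise a hit table, dropping rows above ``evalue_max``."""
    if not isinstance(table, pd.DataFrame):
        table = read_hit_table(table)
    hits = []
    n_dropped = 0
    for row in table.itertuples(index=False):
        if float(row.evalue) > evalue_max:
            n_dropped += 1
            continue
        hits.append(_hit_from_row(row))
    if n_dropped:
        warnings.warn(
            f"dropped {n_dropped} hits above e-value {evalue_max:g}", stacklevel=2
        )
    return hits


# ---------------------------------------------------------------------------
# clustering and best-hit selection
# ---------------------------------------------------------------------------

def cluster_hits(hits: Iterable[ViralHit]) -> list[list[ViralHit]]:
    """Group hits whose intervals overlap or abut on the same chromosome.

    Clustering is the transitive closure of the overlap-or-book-ended
    relation, so clusters are maximal and every hit belongs to exactly
    one.  Output order (and each cluster's member order) is sorted by
    coordinate, independent of input order.
    """
    ordered = sorted(
        hits, key=lambda h: (h.chrom, h.start, h.end, h.subject_id, h.bitscore)
    )
    clusters: list[list[ViralHit]] = []
    span_end = -1
    span_chrom = None
    for hit in ordered:
        if hit.chrom == span_chrom and hit.start <= span_end:
            clusters[-1].append(hit)
            span_end = max(span_end, hit.end)
        else:
            clusters.append([hit])
            span_chrom, span_end = hit.chrom, hit.end
    return clusters


def _best_hit(hits: Sequence[ViralHit]) -> ViralHit:
    """Highest bitscore; ties by lowest e-value, longest alignment, then
    lexicographic subject id."""
    return min(
        hits, key=lambda h: (-h.bitscore, h.evalue, -h.aln_length, h.subject_id)
    )


def select_best(cluster: Sequence[ViralHit]) -> EVECandidate:
    """Reduce a cluster to a candidate spanning its merged interval."""
    if not cluster:
        raise ValueError("empty cluster")
    return EVECandidate(
        chrom=cluster[0].chrom,
        start=min(h.start for h in cluster),
        end=max(h.end for h in cluster),
        best_hit=_best_hit(cluster),
        member_hits=list(cluster),
    )


# ---------------------------------------------------------------------------
# reciprocal filtering
# ---------------------------------------------------------------------------

def reciprocal_filter(
    candidates: Sequence[EVECandidate],
    reciprocal: pd.DataFrame | str | Path | Sequence[ViralHit],
    *,
    evalue_max: float = 1e-6,
    missing_policy: str = "reject",
) -> list[EVECandidate]:
    """Confirm or reject candidates from their reciprocal best hits.

    The reciprocal table is keyed by region id (``chrom:start-end`` of the
    extracted candidate).  A candidate whose best reciprocal hit is viral
    is confirmed; a non-viral best hit marks a host-derived false positive
    (``rejected_host``).  Candidates with no reciprocal row follow
    ``missing_policy``: ``"reject"`` (default) or ``"confirm"``.
    """
    if missing_policy not in ("reject", "confirm"):
        raise ValueError("missing_policy must be 'reject' or 'confirm'")
    if isinstance(reciprocal, (str, Path, pd.DataFrame)):
        rec_hits = load_hits(reciprocal, evalue_max=evalue_max)
    else:
        rec_hits = list(reciprocal)
    by_region: dict[str, list[ViralHit]] = {}
    for hit in rec_hits:
        by_region.setdefault(hit.chrom, []).append(hit)

    known = {c.region_id for c in candidates}
    orphans = set(by_region) - known
    if orphans:
        warnings.warn(
            f"{len(orphans)} reciprocal region ids match no candidate",
            stacklevel=2,
        )

    out = []
    for cand in candidates:
        cand = dataclasses.replace(cand)
        rec = by_region.get(cand.region_id)
        if not rec:
            cand.status = (
                REJECTED_NO_RECIPROCAL if missing_policy == "reject" else CONFIRMED
            )
        else:
            best = _best_hit(rec)
            cand.best_reciprocal = best
            cand.status = CONFIRMED if best.superkingdom == "Viruses" else REJECTED_HOST
        out.append(cand)
    return out


# ---------------------------------------------------------------------------
# joining
# ---------------------------------------------------------------------------

def join_nearby(
    candidates: Sequence[EVECandidate], max_gap: int = 100
) -> list[EVECandidate]:
    """Join confirmed integrations from the same viral species that lie
    closer than ``max_gap`` bp apart on the same chromosome.

    The gap between consecutive integrations is ``start2 - end1`` in
    half-open coordinates; joining requires strictly ``gap < max_gap``
    (gap 99 joins under the default, gap 100 does not) and is transitive.
    The joined integration spans all members and inherits the best hit
    (highest bitscore) among them.  Idempotent: joined output is spaced
    >= max_gap and re-joining changes nothing.
    """
    confirmed = [c for c in candidates if c.status == CONFIRMED]
    groups: dict[tuple[str, str], list[EVECandidate]] = {}
    for cand in confirmed:
        groups.setdefault((cand.chrom, cand.best_hit.species), []).append(cand)

    joined: list[EVECandidate] = []
    for (_, _), members in groups.items():
        members.sort(key=lambda c: (c.start, c.end))
        chain = [members[0]]
        for cand in members[1:]:
            if cand.start - max(c.end for c in chain) < max_gap:
                chain.append(cand)
            else:
                joined.append(_merge_chain(chain))
                chain = [cand]
        joined.append(_merge_chain(chain))
    joined.sort(key=lambda c: (c.chrom, c.start, c.end))
    return joined


def _merge_chain(chain: Sequence[EVECandidate]) -> EVECandidate:
    members = [h for c in chain for h in c.member_hits]
    return EVECandidate(
        chrom=chain[0].chrom,
        start=min(c.start for c in chain),
        end=max(c.end for c in chain),
        best_hit=_best_hit([c.best_hit for c in chain]),
        member_hits=members,
        status=CONFIRMED,
        best_reciprocal=_best_hit(
            [c.best_reciprocal for c in chain if c.best_reciprocal is not None]
        ) if any(c.best_reciprocal for c in chain) else None,
    )


# ---------------------------------------------------------------------------
# family assignment and summary
# ---------------------------------------------------------------------------

def assign_family(
    integration: EVECandidate,
    taxonomy: Mapping[str, tuple[str, str]] | Mapping[str, str],
) -> str:
    """Viral family of the integration's most similar virus.

    ``taxonomy`` maps species to either a family string or a
    ``(family, superkingdom)`` tuple; species absent from the map, or
    mapping to an empty family, yield ``"unclassified"``.
    """
    entry = taxonomy.get(integration.best_hit.species)
    if entry is None:
        return "unclassified"
    family = entry[0] if isinstance(entry, (tuple, list)) else entry
    return family if family else "unclassified"


def summarize(integrations: Sequence[EVECandidate]) -> EVESummary:
    """Family counts and span-length statistics of the final set.

    The median of an even number of lengths is the mean of the two central
    values; an empty input yields an all-zero summary.
    """
    if not integrations:
        return EVESummary(0, {}, 0, 0, 0, 0, 0.0)
    lengths = [c.length_bp for c in integrations]
    family_counts: dict[str, int] = {}
    n_unclassified = 0
    for cand in integrations:
        fam = cand.assigned_family
        if fam == "unclassified":
            n_unclassified += 1
        else:
            family_counts[fam] = family_counts.get(fam, 0) + 1
    return EVESummary(
        n_total=len(integrations),
        family_counts=dict(sorted(family_counts.items())),
        n_unclassified=n_unclassified,
        total_bp=sum(lengths),
        min_bp=min(lengths),
        max_bp=max(lengths),
        median_bp=float(statistics.median(lengths)),
    )


# ---------------------------------------------------------------------------
# one-call refinement
# ---------------------------------------------------------------------------

def refine(
    forward: pd.DataFrame | str | Path,
    reciprocal: pd.DataFrame | str | Path,
    taxonomy: Mapping[str, tuple[str, str]] | Mapping[str, str],
    *,
    evalue_max: float = 1e-6,
    join_gap: int = 100,
    missing_policy: str = "reject",
) -> tuple[list[EVECandidate], EVESummary]:
    """Run the full refinement: load, cluster, select, filter, join,
    assign families and summarise.  Returns the final integrations (with
    families assigned) and their summary."""
    hits = load_hits(forward, evalue_max=evalue_max)
    candidates = [select_best(c) for c in cluster_hits(hits)]
    candidates = reciprocal_filter(
        candidates, reciprocal, evalue_max=evalue_max, missing_policy=missing_policy
    )
    integrations = join_nearby(candidates, max_gap=join_gap)
    for integ in integrations:
        integ.assigned_family = assign_family(integ, taxonomy)
    return integrations, summarize(integrations)
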