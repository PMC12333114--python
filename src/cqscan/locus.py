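"""M-locus delineation and repeat-composition contrast.

The candidate male-determining locus is taken as the minimal interval
covering every male-biased window on the target chromosome — the span of
the CQ <= 0.05 windows.  Its repeat composition is then contrasted with
the genome-wide background: for each repeat class or family, the merged-
coverage fraction inside the locus versus genome-wide, and their ratio
(enrichment).  A hemizygous, recombination-suppressed locus typically
shows a strong excess of LTR retrotransposons.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from typing import Mapping, Sequence

import pandas as pd

from .cq import MALE_BIASED
from .io import label_matches, merged_coverage

__all__ = [
    "LocusCall",
    "RepeatContrast",
    "call_locus",
    "repeat_fraction",
    "repeat_contrast",
]


@dataclasses.dataclass
class LocusCall:
    """A called M-locus candidate (0-based half-open span)."""

    chrom: str
    start: int
    end: int
    n_male_biased: int
    outliers: list[tuple[int, int]] = dataclasses.field(default_factory=list)

    @property
    def span_bp(self) -> int:
        return self.end - self.start

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["span_bp"] = self.span_bp
        d["outliers"] = [list(o) for o in self.outliers]
        return d


def call_locus(
    windows: pd.DataFrame,
    chrom: str,
    max_outlier_distance: int | None = None,
) -> LocusCall | None:
    """Delineate the locus from classified windows on one chromosome.

    Returns the minimal interval covering all male-biased windows, or
    ``None`` when the chromosome carries none.  With
    ``max_outlier_distance`` set, male-biased windows separated from the
    largest cluster by more than that distance are excluded from the span
    and reported as outliers (an extension for noisy data; the default
    ``None`` spans every male-biased window).
    """
    if chrom not in set(windows["chrom"]):
        raise ValueError(f"unknown chromosome {chrom!r}")
    mb = windows[(windows["chrom"] == chrom) & (windows["status"] == MALE_BIASED)]
    if mb.empty:
        return None
    mb = mb.sort_values("start")
    spans = list(zip(mb["start"].astype(int), mb["end"].astype(int)))
    if max_outlier_distance is None:
        return LocusCall(
            chrom=chrom,
            start=spans[0][0],
            end=max(e for _, e in spans),
            n_male_biased=len(spans),
        )
    # cluster by gap; the largest cluster (most windows, ties to the
    # longer span, then the leftmost) is the locus, the rest are outliers
    clusters: list[list[tuple[int, int]]] = [[spans[0]]]
    for s, e in spans[1:]:
        if s - clusters[-1][-1][1] > max_outlier_distance:
            clusters.append([])
        clusters[-1].append((s, e))
    best = max(
        clusters,
        key=lambda c: (len(c), c[-1][1] - c[0][0], -c[0][0]),
    )
    outliers = [iv for c in clusters if c is not best for iv in c]
    return LocusCall(
        chrom=chrom,
        start=best[0][0],
        end=max(e for _, e in best),
        n_male_biased=len(best),
        outliers=outliers,
    )


def repeat_fraction(
    region: tuple[str, int, int],
    annotation: pd.DataFrame,
    label: str | None = None,
) -> float:
    """Merged-coverage fraction of ``region`` by matching repeat intervals.

    ``label`` may name a repeat class, a family or a full ``class/family``
    string; ``None`` measures all repeats.  Overlapping annotation
    intervals are collapsed before measuring, so the result is invariant
    under splitting intervals into adjacent pieces.
    """
    chrom, start, end = region
    if end - start <= 0:
        raise ValueError(f"zero-length region {chrom}:{start}-{end}")
    sub = annotation[annotation["chrom"] == chrom]
    ivs = [
        (int(s), int(e))
        for s, e, name in zip(sub["start"], sub["end"], sub["name"])
        if label_matches(name, label)
    ]
    return merged_coverage(ivs, start, end) / (end - start)


@dataclasses.dataclass
class RepeatContrast:
    """Per-label repeat fractions inside the locus vs. genome-wide.

    ``per_label`` has columns label / fraction_region / fraction_genome /
    enrichment; enrichment is NaN (flagged undefined) when the genome-wide
    background fraction is zero.  ``fraction_repetitive`` is the overall
    merged repeat fraction of the locus across all labels.
    """

    per_label: pd.DataFrame
    fraction_repetitive: float

    def to_dict(self) -> dict:
        return {
            "fraction_repetitive": self.fraction_repetitive,
            "labels": self.per_label.to_dict(orient="records"),
        }


def repeat_contrast(
    locus: LocusCall,
    annotation: pd.DataFrame,
    chrom_sizes: Mapping[str, int],
    labels: Sequence[str],
    include_locus_in_background: bool = True,
) -> RepeatContrast:
    """Contrast the locus's repeat composition against the genome.

    The genome-wide background fraction is merged coverage over the whole
    genome (including the locus itself by default) divided by total genome
    length.  Labels absent from the annotation yield fraction 0 with a
    warning.
    """
    region = (locus.chrom, locus.start, locus.end)
    genome_len = sum(chrom_sizes.values())
    back_len = genome_len if include_locus_in_background else genome_len - locus.span_bp

    rows = []
    for label in labels:
        if not any(label_matches(n, label) for n in annotation["name"]):
            warnings.warn(f"repeat label {label!r} absent from annotation", stacklevel=2)
        frac_region = repeat_fraction(region, annotation, label)
        covered = 0
        for chrom, length in chrom_sizes.items():
            sub = annotation[annotation["chrom"] == chrom]
            ivs = [
                (int(s), int(e))
                for s, e, name in zip(sub["start"], sub["end"], sub["name"])
                if label_matches(name, label)
            ]
            covered += merged_coverage(ivs, 0, length)
            if not include_locus_in_background and chrom == locus.chrom:
                covered -= merged_coverage(ivs, locus.start, locus.end)
        frac_genome = covered / back_len
        enrichment = frac_region / frac_genome if frac_genome > 0 else math.nan
        rows.append((label, frac_region, frac_genome, enrichment))
    per_label = pd.DataFrame(
        rows, columns=["label", "fraction_region", "fraction_genome", "enrichment"]
    )
    return RepeatContrast(
        per_label=per_label,
        fraction_repetitive=repeat_fraction(region, annotation, None),
    )
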