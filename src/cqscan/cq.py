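"""Chromosome-quotient (CQ) core: windowing, counting, masking, classification.

The CQ of a genomic window S is

    CQ_S = F_S / (M_S + c)

where F_S and M_S are the female and male read counts aligned to S and
c is a small pseudocount (default 0.01) that keeps the ratio finite for
male-only sequence.  On balanced male/female sequencing depth, autosomal
windows sit near CQ = 1 while hemizygous male-specific (M-locus) windows
collapse toward 0: a window with CQ <= 0.05 carries at least a ~20-fold
male excess.  Windows are retained only with more than ``min_male_hits``
male reads, so every CQ value rests on real alignment signal.
"""

from __future__ import annotations

import dataclasses
import warnings
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import merge_intervals, read_count_table

__all__ = [
    "STATUSES",
    "CQConfig",
    "CalibrationReport",
    "partition_windows",
    "count_hits",
    "count_hits_from_alignments",
    "apply_mask",
    "compute_cq",
    "classify_cq",
    "filter_and_classify",
    "calibrate",
]

MALE_BIASED = "male_biased"
GREY = "grey"
UNBIASED = "unbiased"
FILTERED_LOW_MALE = "filtered_low_male"
FILTERED_MASKED = "filtered_masked"
STATUSES = (MALE_BIASED, GREY, UNBIASED, FILTERED_LOW_MALE, FILTERED_MASKED)

WINDOW_COLUMNS = [
    "chrom", "start", "end", "female_hits", "male_hits",
    "masked_fraction", "cq", "status",
]


@dataclasses.dataclass
class CQConfig:
    """All CQ-analysis constants.

    window_size
        Window width in bp (default 500).
    pseudocount
        Added to the male count in the denominator (default 0.01).
    male_bias_max
        Upper CQ bound of the male-biased class (default 0.05, inclusive).
    grey_max
        Upper CQ bound of the grey class (default 0.50, inclusive).
    min_male_hits
        A window needs strictly more male hits than this to be retained
        (default 20: a window with exactly 20 male hits is excluded).
    masked_exclude_fraction
        Windows with at least this masked fraction are dropped as
        ``filtered_masked`` (default 1.0: only fully masked windows).
    normalize
        Rescale CQ by (total male hits / total female hits) to correct a
        depth imbalance.  Off by default; balanced libraries need none.
    male_bias_inclusive
        Whether CQ exactly at ``male_bias_max`` is male-biased (default
        True, matching the plotted male-biased set).
    mapq_min
        Minimum mapping quality when counting from alignment files.
    """

    window_size: int = 500
    pseudocount: float = 0.01
    male_bias_max: float = 0.05
    grey_max: float = 0.50
    min_male_hits: int = 20
    masked_exclude_fraction: float = 1.0
    normalize: bool = False
    male_bias_inclusive: bool = True
    mapq_min: int = 0

    def __post_init__(self) -> None:
        if self.window_size <= 0:
            raise ValueError("window_size must be positive")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be positive")
        if not (0 < self.male_bias_max < self.grey_max):
            raise ValueError("need 0 < male_bias_max < grey_max")
        if self.min_male_hits < 0:
            raise ValueError("min_male_hits must be >= 0")
        if not (0 < self.masked_exclude_fraction <= 1):
            raise ValueError("masked_exclude_fraction must be in (0, 1]")


# ---------------------------------------------------------------------------
# windowing
# ---------------------------------------------------------------------------

def partition_windows(
    chrom_sizes: Mapping[str, int], window_size: int = 500
) -> pd.DataFrame:
    """Tile each chromosome with contiguous half-open windows from 0.

    The final window of a chromosome may be shorter than ``window_size``;
    it is kept and classified like any other.
    """
    if window_size <= 0:
        raise ValueError("window_size must be positive")
    frames = []
    for chrom, length in chrom_sizes.items():
        if length <= 0:
            raise ValueError(f"chromosome {chrom!r} has non-positive length {length}")
        starts = np.arange(0, length, window_size, dtype=np.int64)
        ends = np.minimum(starts + window_size, length)
        frames.append(pd.DataFrame({"chrom": chrom, "start": starts, "end": ends}))
    windows = pd.concat(frames, ignore_index=True)
    windows["female_hits"] = 0
    windows["male_hits"] = 0
    windows["masked_fraction"] = 0.0
    windows["cq"] = np.nan
    windows["status"] = UNBIASED
    return windows


# ---------------------------------------------------------------------------
# counting
# ---------------------------------------------------------------------------

def count_hits(windows: pd.DataFrame, counts: pd.DataFrame | str | Path) -> pd.DataFrame:
    """Fill female/male hit counts from a precomputed per-window table.

    The table must carry the same (chrom, start, end) windows; windows
    absent from the table get zero counts, rows for chromosomes unknown to
    ``windows`` are skipped with a warning.
    """
    if not isinstance(counts, pd.DataFrame):
        counts = read_count_table(counts)
    known = set(windows["chrom"].unique())
    foreign = set(counts["chrom"].unique()) - known
    if foreign:
        warnings.warn(
            f"count table chromosomes absent from windows, skipped: {sorted(foreign)}",
            stacklevel=2,
        )
        counts = counts[counts["chrom"].isin(known)]
    out = windows.drop(columns=["female_hits", "male_hits"]).merge(
        counts[["chrom", "start", "end", "female_hits", "male_hits"]],
        on=["chrom", "start", "end"],
        how="left",
    )
    out[["female_hits", "male_hits"]] = (
        out[["female_hits", "male_hits"]].fillna(0).astype(int)
    )
    return out[WINDOW_COLUMNS]


def _counts_from_alignment(
    path: str | Path, windows: pd.DataFrame, window_size: int, mapq_min: int
) -> dict[str, np.ndarray]:
    """Per-chromosome count arrays from a SAM/BAM/CRAM file.

    Each primary mapped record is attributed to the single window that
    contains its leftmost aligned base; unmapped, secondary and
    supplementary records are excluded, as are records below ``mapq_min``.
    """
    import pysam

    n_windows = windows.groupby("chrom", sort=False).size().to_dict()
    counts = {c: np.zeros(n, dtype=np.int64) for c, n in n_windows.items()}
    skipped_chroms: set[str] = set()
    with pysam.AlignmentFile(str(path), check_sq=False) as af:
        for rec in af.fetch(until_eof=True):
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            if rec.mapping_quality < mapq_min:
                continue
            chrom = rec.reference_name
            arr = counts.get(chrom)
            if arr is None:
                skipped_chroms.add(chrom)
                continue
            idx = rec.reference_start // window_size
            if 0 <= idx < arr.shape[0]:
                arr[idx] += 1
    if skipped_chroms:
        warnings.warn(
            f"alignment chromosomes absent from windows, skipped: "
            f"{sorted(skipped_chroms)}",
            stacklevel=3,
        )
    return counts


def count_hits_from_alignments(
    windows: pd.DataFrame,
    female: str | Path,
    male: str | Path,
    *,
    window_size: int | None = None,
    mapq_min: int = 0,
) -> pd.DataFrame:
    """Fill female/male hit counts from one alignment file per sex."""
    if window_size is None:
        window_size = int((windows["end"] - windows["start"]).max())
    out = windows.copy()
    for sex, path in (("female_hits", female), ("male_hits", male)):
        per_chrom = _counts_from_alignment(path, windows, window_size, mapq_min)
        col = np.concatenate(
            [per_chrom[c] for c in windows["chrom"].unique()]
        )
        out[sex] = col
    return out[WINDOW_COLUMNS]


# ---------------------------------------------------------------------------
# masking
# ---------------------------------------------------------------------------

def apply_mask(
    windows: pd.DataFrame,
    masks: pd.DataFrame,
    masked_exclude_fraction: float = 1.0,
) -> pd.DataFrame:
    """Set per-window masked fractions from a BED-like mask table.

    ``masked_fraction`` is the merged mask coverage of the window divided
    by the window length; windows at or above ``masked_exclude_fraction``
    are flagged ``filtered_masked`` (their CQ stays undefined).
    """
    out = windows.reset_index(drop=True).copy()
    out["masked_fraction"] = 0.0
    covered = np.zeros(len(out), dtype=np.int64)
    for chrom, group in out.groupby("chrom", sort=False):
        chrom_masks = masks[masks["chrom"] == chrom]
        if chrom_masks.empty:
            continue
        merged = merge_intervals(
            zip(chrom_masks["start"].astype(int), chrom_masks["end"].astype(int))
        )
        starts = group["start"].to_numpy()
        ends = group["end"].to_numpy()
        cov = np.zeros(len(group), dtype=np.int64)
        for ms, me in merged:
            cov += np.clip(
                np.minimum(ends, me) - np.maximum(starts, ms), 0, None
            )
        covered[group.index.to_numpy()] = cov
    lengths = (out["end"] - out["start"]).to_numpy()
    out["masked_fraction"] = covered / lengths
    fully = out["masked_fraction"] >= masked_exclude_fraction
    out.loc[fully, "status"] = FILTERED_MASKED
    out.loc[fully, "cq"] = np.nan
    return out


# ---------------------------------------------------------------------------
# the statistic
# ---------------------------------------------------------------------------

def compute_cq(female_hits, male_hits, pseudocount: float = 0.01):
    """CQ = F / (M + pseudocount); accepts scalars or arrays.

    Strictly increasing in F, strictly decreasing in M; the pseudocount
    keeps the quotient finite when the female library contributes nothing.
    """
    f = np.asarray(female_hits, dtype=float)
    m = np.asarray(male_hits, dtype=float)
    if (f < 0).any() or (m < 0).any():
        raise ValueError("hit counts must be non-negative")
    cq = f / (m + pseudocount)
    if np.isscalar(female_hits) and np.isscalar(male_hits):
        return float(cq)
    return cq


def classify_cq(cq: float, config: CQConfig | None = None) -> str:
    """Class of a defined CQ value: male_biased, grey or unbiased."""
    config = config or CQConfig()
    if config.male_bias_inclusive:
        if cq <= config.male_bias_max:
            return MALE_BIASED
    elif cq < config.male_bias_max:
        return MALE_BIASED
    if cq <= config.grey_max:
        return GREY
    return UNBIASED


def filter_and_classify(
    windows: pd.DataFrame, config: CQConfig | None = None
) -> pd.DataFrame:
    """Apply the retention filter, compute CQ and classify every window.

    Fully masked windows keep their ``filtered_masked`` status; of the
    rest, windows with male hits <= ``min_male_hits`` become
    ``filtered_low_male`` with undefined CQ, and retained windows are
    partitioned into male_biased / grey / unbiased by their CQ.
    """
    config = config or CQConfig()
    out = windows.copy()
    masked = out["status"] == FILTERED_MASKED
    low_male = ~masked & (out["male_hits"] <= config.min_male_hits)
    out.loc[low_male, "status"] = FILTERED_LOW_MALE
    retained = ~masked & ~low_male
    cq = compute_cq(
        out.loc[retained, "female_hits"].to_numpy(),
        out.loc[retained, "male_hits"].to_numpy(),
        config.pseudocount,
    )
    if config.normalize:
        total_f = out["female_hits"].sum()
        total_m = out["male_hits"].sum()
        if total_f > 0:
            cq = cq * (total_m / total_f)
    out.loc[retained, "cq"] = cq
    out.loc[~retained, "cq"] = np.nan
    out.loc[retained, "status"] = [classify_cq(v, config) for v in cq]
    return out[WINDOW_COLUMNS]


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class CalibrationReport:
    """Autosomal CQ calibration summary.

    ``per_chrom`` maps each autosome to its mean and median CQ over
    retained windows; ``male_female_ratio`` is the total male over total
    female mapped-count ratio, usable as a normalisation factor; and
    ``near_one`` records whether every autosomal mean and median lies
    within ``tolerance`` of 1, in which case no normalisation is needed.
    """

    per_chrom: dict[str, dict[str, float]]
    male_female_ratio: float
    near_one: bool
    tolerance: float

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def calibrate(
    windows: pd.DataFrame,
    autosome_names: Sequence[str],
    tolerance: float = 0.2,
) -> CalibrationReport:
    """Summarise autosomal CQ to check whether normalisation is needed.

    Uses all windows with a defined CQ (every retained class, including
    unbiased).  Raises ``ValueError`` if a named autosome has no retained
    window.
    """
    retained = windows[windows["cq"].notna()]
    per_chrom: dict[str, dict[str, float]] = {}
    near = True
    for chrom in autosome_names:
        sub = retained[retained["chrom"] == chrom]
        if sub.empty:
            raise ValueError(f"no retained windows on autosome {chrom!r}")
        mean = float(sub["cq"].mean())
        median = float(sub["cq"].median())
        per_chrom[chrom] = {"mean_cq": mean, "median_cq": median}
        near = near and abs(mean - 1) <= tolerance and abs(median - 1) <= tolerance
    total_f = windows["female_hits"].sum()
    ratio = float(windows["male_hits"].sum() / total_f) if total_f else float("inf")
    return CalibrationReport(
        per_chrom=per_chrom,
        male_female_ratio=ratio,
        near_one=near,
        tolerance=tolerance,
    )
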