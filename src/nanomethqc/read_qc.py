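"""Read filtering and read-accuracy statistics for long-read QC.

Two per-read accuracy measures are computed. The *estimated* accuracy is
derived from basecalled Phred qualities,

    estimated = 1 - (1/N) * sum_i 10^(-q_i / 10),

and the *observed* accuracy from the alignment against the reference,

    observed = N(mat) / N(total),
    N(total) = N(sub) + N(mat) + N(ins) + N(del).

Soft/hard clips and reference skips contribute to neither count. Read-level
quality for filtering is the Q-scale twin of the estimated accuracy:
``-10 * log10(mean per-base error probability)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .core_io import AlignedModRead, FastqRead, GenomeSequence

__all__ = [
    "AlignmentTally",
    "ReadAccuracy",
    "AccuracySummary",
    "FilterLog",
    "estimated_accuracy",
    "read_quality",
    "tally_alignment",
    "observed_accuracy",
    "filter_reads",
    "accuracy_summary",
    "length_metric_correlation",
]


@dataclass(frozen=True)
class AlignmentTally:
    """Base-level alignment event counts for one read."""

    n_mat: int
    n_sub: int
    n_ins: int
    n_del: int

    def __post_init__(self) -> None:
        if min(self.n_mat, self.n_sub, self.n_ins, self.n_del) < 0:
            raise ValueError("tally counts must be non-negative")

    @property
    def n_total(self) -> int:
        return self.n_mat + self.n_sub + self.n_ins + self.n_del


@dataclass(frozen=True)
class ReadAccuracy:
    read_id: str
    length: int
    estimated: float
    observed: float | None  # absent for unmapped reads


@dataclass(frozen=True)
class AccuracySummary:
    mean: float
    mode: float
    histogram: list[tuple[float, float]]  # (bin center, density); sums to 1


def estimated_accuracy(qualities: Sequence[int]) -> float:
    """Per-read accuracy estimated from Phred base qualities."""
    q = np.asarray(qualities, dtype=float)
    if q.size == 0:
        raise ValueError("empty quality vector")
    if np.any(q < 0):
        raise ValueError("Phred qualities must be >= 0")
    return float(1.0 - np.mean(10.0 ** (-q / 10.0)))


def read_quality(qualities: Sequence[int]) -> float:
    """Read-level Phred score: -10*log10 of the mean per-base error probability."""
    q = np.asarray(qualities, dtype=float)
    if q.size == 0:
        raise ValueError("empty quality vector")
    return float(-10.0 * np.log10(np.mean(10.0 ** (-q / 10.0))))


def tally_alignment(read: AlignedModRead, ref: GenomeSequence) -> AlignmentTally:
    """Count matches/substitutions/insertions/deletions against the reference.

    M operations are split by base comparison; ``=``/``X`` count directly.
    Positions whose reference base is N are skipped from both match and
    substitution counts.
    """
    if read.ref_end > ref.length:
        raise ValueError(
            f"read {read.read_id} aligned span [{read.ref_start},{read.ref_end}) "
            f"exceeds contig {ref.name} length {ref.length}"
        )
    ref_bytes = np.frombuffer(ref.sequence.encode(), dtype=np.uint8)
    query_bytes = np.frombuffer(read.sequence.upper().encode(), dtype=np.uint8)
    n_mat = n_sub = n_ins = n_del = 0
    q = 0
    r = read.ref_start
    for op, n in read.cigar:
        if op == "M":
            rb = ref_bytes[r : r + n]
            qb = query_bytes[q : q + n]
            informative = rb != ord("N")
            n_mat += int(np.count_nonzero((rb == qb) & informative))
            n_sub += int(np.count_nonzero((rb != qb) & informative))
            q += n
            r += n
        elif op == "=":
            informative = ref_bytes[r : r + n] != ord("N")
            n_mat += int(np.count_nonzero(informative))
            q += n
            r += n
        elif op == "X":
            informative = ref_bytes[r : r + n] != ord("N")
            n_sub += int(np.count_nonzero(informative))
            q += n
            r += n
        elif op == "I":
            n_ins += n
            q += n
        elif op == "D":
            n_del += n
            r += n
        elif op == "S":
            q += n
        elif op == "N":
            r += n
        # H/P consume nothing
    return AlignmentTally(n_mat=n_mat, n_sub=n_sub, n_ins=n_ins, n_del=n_del)


def observed_accuracy(tally: AlignmentTally) -> float:
    if tally.n_total == 0:
        raise ValueError("observed accuracy undefined for an empty tally")
    return tally.n_mat / tally.n_total


@dataclass
class FilterLog:
    """Per-reason accounting of a filtering pass."""

    kept: int = 0
    fully_trimmed: int = 0
    too_short: int = 0
    low_quality: int = 0

    @property
    def rejected(self) -> int:
        return self.fully_trimmed + self.too_short + self.low_quality

    @property
    def total(self) -> int:
        return self.kept + self.rejected

    def as_dict(self) -> dict[str, int]:
        return {
            "kept": self.kept,
            "fully_trimmed": self.fully_trimmed,
            "too_short": self.too_short,
            "low_quality": self.low_quality,
        }


def filter_reads(
    reads: Iterable[FastqRead],
    trim: int = 50,
    min_length: int = 200,
    min_q: float = 7.0,
) -> tuple[list[FastqRead], FilterLog]:
    """End-trim then length/quality filter raw reads.

    Each read is first trimmed by ``trim`` bases at both ends (qualities with
    the sequence), then discarded if the trimmed length is below
    ``min_length`` or its read-level Phred quality is below ``min_q``.
    """
    kept: list[FastqRead] = []
    log = FilterLog()
    for read in reads:
        if len(read.sequence) <= 2 * trim:
            log.fully_trimmed += 1
            continue
        end = len(read.sequence) - trim
        trimmed = FastqRead(read.read_id, read.sequence[trim:end], read.qualities[trim:end])
        if len(trimmed.sequence) < min_length:
            log.too_short += 1
            continue
        if read_quality(trimmed.qualities) < min_q:
            log.low_quality += 1
            continue
        kept.append(trimmed)
        log.kept += 1
    return kept, log


def accuracy_summary(
    values: Sequence[float], bin_width: float = 0.005
) -> AccuracySummary:
    """Mean, histogram mode and normalized density of per-read accuracies.

    The histogram tiles [0, 1] with fixed-width bins; the mode is the center
    of the maximal-count bin with ties broken toward the lower bin.
    """
    vals = np.asarray(values, dtype=float)
    if vals.size == 0:
        raise ValueError("empty accuracy collection")
    if np.any((vals < 0) | (vals > 1)):
        raise ValueError("accuracies must lie in [0, 1]")
    n_bins = int(round(1.0 / bin_width))
    counts, edges = np.histogram(vals, bins=n_bins, range=(0.0, 1.0))
    centers = (edges[:-1] + edges[1:]) / 2.0
    density = counts / counts.sum()
    mode = float(centers[int(np.argmax(counts))])  # argmax picks the lower tied bin
    return AccuracySummary(
        mean=float(vals.mean()),
        mode=mode,
        histogram=list(zip(centers.tolist(), density.tolist())),
    )


def length_metric_correlation(
    lengths: Sequence[float], metric: Sequence[float]
) -> float:
    """Pearson r between read length and a per-read metric (>=3 pairs)."""
    x = np.asarray(lengths, dtype=float)
    y = np.asarray(metric, dtype=float)
    if x.size != y.size:
        raise ValueError("length and metric vectors differ in size")
    if x.size < 3:
        raise ValueError("need at least 3 paired values for a correlation")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("undefined correlation: zero variance in one variable")
    return float(stats.pearsonr(x, y).statistic)
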