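"""Cross-dataset statistics: genome recovery, subsampling saturation curves,
regional Pearson correlation (optionally restricted to shared CpG sites),
GC-bias coverage profiles, and point liftover between assemblies.

Subsampling keeps each read independently with probability equal to the
requested proportion (seeded Bernoulli), so a proportion of 1.0 reproduces
the full dataset exactly and curves are reproducible from a base seed.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .core_io import (
    AlignedModRead,
    BedMethylRecord,
    ChainAlignment,
    GenomeSequence,
    REF_CONSUMING,
)
from .methylation import (
    CpGSite,
    RegionMethylation,
    bin_methylation,
    classify_call,
    promoter_methylation,
)

__all__ = [
    "SubsampleCurve",
    "GCBiasProfile",
    "CorrelationResult",
    "genome_recovery",
    "subsample_reads",
    "recovery_curve",
    "methylation_stability_curve",
    "region_correlation",
    "shared_site_correlation",
    "gc_bias_profile",
    "liftover_sites",
]

DEFAULT_PROPORTIONS = tuple(np.round(np.arange(0.1, 1.01, 0.1), 2))

logger = logging.getLogger(__name__)


@dataclass
class SubsampleCurve:
    """Statistic per (proportion, replicate), with the RNG seeds used."""

    proportions: list[float]
    replicates: int
    values: list[list[float | None]]  # [proportion][replicate]
    seeds: list[list[int]]

    def means(self) -> list[float]:
        return [
            float(np.mean([v for v in row if v is not None])) for row in self.values
        ]


@dataclass(frozen=True)
class GCBiasProfile:
    """Mean and normalized coverage per integer GC percent of 1 kb bins."""

    bin_size: int
    mean_coverage: dict[int, float]
    normalized: dict[int, float]
    grand_mean: float


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    n: int


def _ref_map(
    ref: GenomeSequence | Mapping[str, GenomeSequence] | Sequence[GenomeSequence]
) -> dict[str, GenomeSequence]:
    if isinstance(ref, GenomeSequence):
        return {ref.name: ref}
    if isinstance(ref, Mapping):
        return dict(ref)
    return {c.name: c for c in ref}


def genome_recovery(
    reads: Iterable[AlignedModRead],
    ref: GenomeSequence | Mapping[str, GenomeSequence] | Sequence[GenomeSequence],
) -> float:
    """Fraction of reference bases covered by >= 1 aligned base.

    Deletions within a read span the reference and therefore cover; inserted
    and clipped bases do not. Empty input yields 0.0.
    """
    contigs = _ref_map(ref)
    masks = {name: np.zeros(c.length, dtype=bool) for name, c in contigs.items()}
    for read in reads:
        mask = masks.get(read.contig)
        if mask is None:
            continue
        if not any(op == "N" for op, _ in read.cigar):
            # M/=/X/D spans are contiguous on the reference
            mask[read.ref_start : read.ref_end] = True
            continue
        r = read.ref_start
        for op, n in read.cigar:
            if op in "M=XD":
                mask[r : r + n] = True
                r += n
            elif op == "N":
                r += n
    total = sum(m.size for m in masks.values())
    covered = sum(int(m.sum()) for m in masks.values())
    if covered == 0:
        logger.warning("genome_recovery: no aligned bases over the reference")
    return covered / total if total else 0.0


def subsample_reads(
    reads: Sequence[AlignedModRead], proportion: float, seed: int
) -> list[AlignedModRead]:
    """Keep each read independently with the given probability (seeded)."""
    if not 0.0 < proportion <= 1.0:
        raise ValueError("proportion must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    keep = rng.random(len(reads)) < proportion
    return [r for r, k in zip(reads, keep) if k]


def _replicate_seeds(
    base_seed: int, n_prop: int, replicates: int
) -> list[list[int]]:
    rng = np.random.default_rng(base_seed)
    return rng.integers(0, 2**31 - 1, size=(n_prop, replicates)).tolist()


def recovery_curve(
    reads: Sequence[AlignedModRead],
    ref: Mapping[str, GenomeSequence] | Sequence[GenomeSequence],
    proportions: Sequence[float] = DEFAULT_PROPORTIONS,
    replicates: int = 10,
    base_seed: int = 0,
) -> SubsampleCurve:
    """Genome recovery rate per subsampling replicate per proportion."""
    seeds = _replicate_seeds(base_seed, len(proportions), replicates)
    values: list[list[float | None]] = []
    for i, p in enumerate(proportions):
        row: list[float | None] = []
        for j in range(replicates):
            subset = subsample_reads(reads, p, seeds[i][j])
            row.append(genome_recovery(subset, ref))
        values.append(row)
    return SubsampleCurve(list(map(float, proportions)), replicates, values, seeds)


def methylation_stability_curve(
    reads: Sequence[AlignedModRead],
    proportions: Sequence[float] = DEFAULT_PROPORTIONS,
    replicates: int = 10,
    base_seed: int = 0,
    threshold: float = 0.5,
    lower: float | None = None,
) -> SubsampleCurve:
    """Overall 5mC percentage per subsampling replicate per proportion.

    Pooling calls over reads is identical to pooling the corresponding
    site pileup, so per-read call counts are tallied once up front.
    """
    per_read: list[tuple[int, int]] = []
    for read in reads:
        m = c = 0
        for call in read.mod_calls:
            kind = classify_call(call.probability, threshold, lower)
            if kind == "modified":
                m += 1
            elif kind == "canonical":
                c += 1
        per_read.append((m, m + c))
    mods = np.array([t[0] for t in per_read])
    valids = np.array([t[1] for t in per_read])
    seeds = _replicate_seeds(base_seed, len(proportions), replicates)
    values: list[list[float | None]] = []
    for i, p in enumerate(proportions):
        if not 0.0 < p <= 1.0:
            raise ValueError("proportion must lie in (0, 1]")
        row: list[float | None] = []
        for j in range(replicates):
            rng = np.random.default_rng(seeds[i][j])
            keep = rng.random(len(reads)) < p
            valid = int(valids[keep].sum())
            row.append(100.0 * mods[keep].sum() / valid if valid else None)
        values.append(row)
    return SubsampleCurve(list(map(float, proportions)), replicates, values, seeds)


def region_correlation(
    a: Sequence[RegionMethylation], b: Sequence[RegionMethylation]
) -> CorrelationResult:
    """Pearson r between two region sets keyed by interval (complete cases)."""
    index_b = {
        (r.interval.contig, r.interval.start, r.interval.end): r for r in b
    }
    xs, ys = [], []
    for ra in a:
        rb = index_b.get((ra.interval.contig, ra.interval.start, ra.interval.end))
        if rb is None:
            continue
        pa, pb = ra.proportion, rb.proportion
        if pa is None or pb is None:
            continue
        xs.append(pa)
        ys.append(pb)
    if len(xs) < 3:
        raise ValueError("undefined correlation: fewer than 3 shared regions")
    if np.ptp(xs) == 0 or np.ptp(ys) == 0:
        raise ValueError("undefined correlation: zero variance")
    return CorrelationResult(r=float(stats.pearsonr(xs, ys).statistic), n=len(xs))


def shared_site_correlation(
    cpgs_a: Sequence[CpGSite],
    cpgs_b: Sequence[CpGSite],
    ref: Mapping[str, GenomeSequence] | Sequence[GenomeSequence],
    level: str = "bins",
    bin_size: int = 100_000,
    tss=None,
    upstream: int = 5000,
) -> CorrelationResult:
    """Regional correlation recomputed from CpG sites present in both datasets.

    Each dataset's regional proportions are rebuilt using only the shared
    site positions before correlating, so coverage differences between
    platforms cannot drive the comparison.
    """
    keys_a = {(c.contig, c.position) for c in cpgs_a if c.valid_coverage > 0}
    keys_b = {(c.contig, c.position) for c in cpgs_b if c.valid_coverage > 0}
    shared = keys_a & keys_b
    sub_a = [c for c in cpgs_a if (c.contig, c.position) in shared]
    sub_b = [c for c in cpgs_b if (c.contig, c.position) in shared]
    if level == "bins":
        regions_a = bin_methylation(sub_a, ref, bin_size)
        regions_b = bin_methylation(sub_b, ref, bin_size)
    elif level == "promoters":
        if tss is None:
            raise ValueError("promoter-level correlation requires TSS records")
        regions_a = promoter_methylation(sub_a, tss, ref, upstream)
        regions_b = promoter_methylation(sub_b, tss, ref, upstream)
    else:
        raise ValueError(f"unknown level {level!r}")
    return region_correlation(regions_a, regions_b)


def gc_bias_profile(
    ref: Mapping[str, GenomeSequence] | Sequence[GenomeSequence],
    depth: Sequence[tuple[str, int, int, float]],
    bin_size: int = 1000,
    gc_range: tuple[int, int] = (10, 60),
    max_n_fraction: float = 0.5,
) -> GCBiasProfile:
    """Coverage as a function of bin GC content, normalized within ``gc_range``.

    ``depth`` rows are (contig, start, end, summed depth) over bins tiling
    the reference. Each bin's integer GC percent is computed over its non-N
    bases (bins with more than ``max_n_fraction`` N are dropped); per-level
    mean coverage is normalized by the mean of the per-level means whose GC
    lies within ``gc_range``.
    """
    contigs = _ref_map(ref)
    per_level: dict[int, list[float]] = defaultdict(list)
    for contig_name, start, end, total in depth:
        contig = contigs.get(contig_name)
        if contig is None:
            raise ValueError(f"depth row names unknown contig {contig_name!r}")
        if end - start != bin_size and end != contig.length:
            raise ValueError(
                f"bin {contig_name}:{start}-{end} does not match bin size {bin_size}"
            )
        window = np.frombuffer(
            contig.sequence[start:end].encode(), dtype=np.uint8
        )
        n_n = int(np.count_nonzero(window == ord("N")))
        informative = window.size - n_n
        if informative == 0 or n_n / window.size > max_n_fraction:
            continue
        gc = int(
            round(
                100.0
                * np.count_nonzero((window == ord("G")) | (window == ord("C")))
                / informative
            )
        )
        per_level[gc].append(total / (end - start))
    mean_coverage = {gc: float(np.mean(v)) for gc, v in sorted(per_level.items())}
    lo, hi = gc_range
    in_range = [m for gc, m in mean_coverage.items() if lo <= gc <= hi]
    if not in_range:
        raise ValueError(f"no bins with GC content within {gc_range}")
    grand = float(np.mean(in_range))
    normalized = {
        gc: m / grand for gc, m in mean_coverage.items() if lo <= gc <= hi
    }
    return GCBiasProfile(bin_size, mean_coverage, normalized, grand)


def liftover_sites(
    records: Sequence[BedMethylRecord], chains: Sequence[ChainAlignment]
) -> tuple[list[BedMethylRecord], list[BedMethylRecord]]:
    """Map single-base records through chain alignments.

    A position inside an aligned block maps by offset into the target
    assembly (coordinates and strand flipped when the chain's target strand
    is '-'); positions inside gaps or outside every chain are returned
    unmapped. When several chains cover a position the highest-score chain
    wins; a position in that chain's gap stays unmapped.
    """
    by_source: dict[str, list[ChainAlignment]] = defaultdict(list)
    for chain in chains:
        if chain.source_strand != "+":
            raise ValueError("chains with '-' source strand are not supported")
        by_source[chain.source_name].append(chain)
    for lst in by_source.values():
        lst.sort(key=lambda c: -c.score)

    mapped: list[BedMethylRecord] = []
    unmapped: list[BedMethylRecord] = []
    for rec in records:
        chain = next(
            (
                c
                for c in by_source.get(rec.contig, [])
                if c.source_start <= rec.start < c.source_end
            ),
            None,
        )
        target = _map_position(chain, rec.start) if chain is not None else None
        if target is None:
            unmapped.append(rec)
            continue
        pos, flip = target
        strand = rec.strand
        if flip and strand in "+-":
            strand = "-" if strand == "+" else "+"
        mapped.append(
            BedMethylRecord(
                contig=chain.target_name,
                start=pos,
                strand=strand,
                coverage=rec.coverage,
                percent_methylated=rec.percent_methylated,
            )
        )
    return mapped, unmapped


def _map_position(chain: ChainAlignment, pos: int) -> tuple[int, bool] | None:
    s = chain.source_start
    t = chain.target_start
    for block in chain.blocks:
        if s <= pos < s + block.size:
            t_pos = t + (pos - s)
            if chain.target_strand == "-":
                return chain.target_size - 1 - t_pos, True
            return t_pos, False
        s += block.size + block.dt
        t += block.size + block.dq
    return None
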