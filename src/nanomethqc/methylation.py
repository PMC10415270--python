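"""Site-level 5mC pileups, strand-collapsed CpG sites and regional methylation.

Modification calls are projected through each read's CIGAR onto the
reference. A call with probability >= ``threshold`` counts as modified and
< ``1 - threshold`` as canonical (ties classify as modified); with the
default single threshold of 0.5 no call is ambiguous, while a dual-threshold
mode (e.g. 0.33/0.66) discards mid-probability calls.

A CpG site is a reference CG dinucleotide: the forward-strand C at position
i and the reverse-strand C (the G at i+1) are pooled into a single site, and
a site counts as *covered* only when both strands carry at least one read.
Regional methylation (100 kb bins, 5 kb promoters) is the coverage-weighted
pooled ratio sum(modified) / sum(valid), so bins aggregate exactly to the
genome-wide figure.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .core_io import (
    AlignedModRead,
    BedMethylRecord,
    GenomeSequence,
    GenomicInterval,
    query_to_ref_map,
)

__all__ = [
    "SiteMethylation",
    "CpGSite",
    "RegionMethylation",
    "classify_call",
    "pileup_sites",
    "collapse_cpg",
    "cpg_positions",
    "covered_cpg_fraction",
    "bin_methylation",
    "promoter_methylation",
    "per_read_methylation",
    "overall_methylation",
    "sites_to_bedmethyl",
    "cpgs_to_bedmethyl",
    "bedmethyl_to_cpgs",
    "write_regions_tsv",
    "read_regions_tsv",
]

logger = logging.getLogger(__name__)


@dataclass
class SiteMethylation:
    """Per-strand pileup counts at one reference position."""

    contig: str
    position: int
    strand: str
    n_modified: int = 0
    n_canonical: int = 0
    n_ambiguous: int = 0

    @property
    def valid_coverage(self) -> int:
        return self.n_modified + self.n_canonical

    @property
    def proportion(self) -> float | None:
        if self.valid_coverage == 0:
            return None
        return self.n_modified / self.valid_coverage


@dataclass
class CpGSite:
    """Strand-collapsed CG dinucleotide; position is the forward-strand C."""

    contig: str
    position: int
    n_modified: int = 0
    n_canonical: int = 0
    forward_coverage: int = 0
    reverse_coverage: int = 0

    @property
    def valid_coverage(self) -> int:
        return self.n_modified + self.n_canonical

    @property
    def proportion(self) -> float | None:
        if self.valid_coverage == 0:
            return None
        return self.n_modified / self.valid_coverage


@dataclass
class RegionMethylation:
    """Pooled methylation over an interval (bin or promoter)."""

    interval: GenomicInterval
    n_modified: int
    n_valid: int
    n_sites: int

    @property
    def proportion(self) -> float | None:
        """Percent methylated, or None when the region has no valid calls."""
        if self.n_valid == 0:
            return None
        return 100.0 * self.n_modified / self.n_valid


def classify_call(
    probability: float, threshold: float = 0.5, lower: float | None = None
) -> str:
    """'modified', 'canonical' or 'ambiguous' under the threshold policy.

    ``threshold`` is the modified cutoff (ties -> modified); ``lower``
    defaults to ``1 - threshold`` (single symmetric threshold).
    """
    lo = (1.0 - threshold) if lower is None else lower
    if probability >= threshold:
        return "modified"
    if probability < lo:
        return "canonical"
    return "ambiguous"


def pileup_sites(
    reads: Iterable[AlignedModRead],
    ref: GenomeSequence | Mapping[str, GenomeSequence],
    threshold: float = 0.5,
    lower: float | None = None,
    include_non_primary: bool = False,
) -> list[SiteMethylation]:
    """Project modification calls onto the reference and tally per (pos, strand).

    Calls landing on deleted/clipped bases are dropped; a call projecting
    outside its contig raises (corrupt alignment). Only positions with at
    least one projected call are emitted, sorted by (contig, position, strand).
    """
    contigs = {ref.name: ref} if isinstance(ref, GenomeSequence) else dict(ref)
    acc: dict[tuple[str, int, str], SiteMethylation] = {}
    for read in reads:
        if not read.mod_calls or (not read.is_primary and not include_non_primary):
            continue
        contig = contigs.get(read.contig)
        if contig is None:
            raise ValueError(f"read {read.read_id}: unknown contig {read.contig!r}")
        qmap = query_to_ref_map(read)
        length = read.query_length
        for call in read.mod_calls:
            stored = call.offset if read.strand == "+" else length - 1 - call.offset
            ref_pos = int(qmap[stored])
            if ref_pos < 0:
                continue  # call sits on an inserted/clipped base
            if ref_pos >= contig.length:
                raise ValueError(
                    f"read {read.read_id}: call projects to {ref_pos} beyond contig "
                    f"{contig.name} length {contig.length}"
                )
            key = (read.contig, ref_pos, read.strand)
            site = acc.get(key)
            if site is None:
                site = acc[key] = SiteMethylation(read.contig, ref_pos, read.strand)
            kind = classify_call(call.probability, threshold, lower)
            if kind == "modified":
                site.n_modified += 1
            elif kind == "canonical":
                site.n_canonical += 1
            else:
                site.n_ambiguous += 1
    return [acc[k] for k in sorted(acc)]


def cpg_positions(ref: GenomeSequence) -> np.ndarray:
    """0-based forward-strand C positions of every CG dinucleotide."""
    seq = np.frombuffer(ref.sequence.encode(), dtype=np.uint8)
    hits = (seq[:-1] == ord("C")) & (seq[1:] == ord("G"))
    return np.flatnonzero(hits)


def collapse_cpg(
    sites: Iterable[SiteMethylation],
    ref: GenomeSequence | Mapping[str, GenomeSequence],
) -> list[CpGSite]:
    """Pool each reference CG's forward-C and reverse-C (the G) strand sites.

    Strand sites that do not sit at a reference CG are excluded; pooled
    counts are exactly the sum of the two constituent strand sites.
    """
    contigs = {ref.name: ref} if isinstance(ref, GenomeSequence) else dict(ref)
    cg_index: dict[str, set[int]] = {
        name: set(cpg_positions(c).tolist()) for name, c in contigs.items()
    }
    acc: dict[tuple[str, int], CpGSite] = {}
    n_excluded = 0
    for site in sites:
        cgs = cg_index.get(site.contig)
        if cgs is None:
            n_excluded += 1
            continue
        if site.strand == "+" and site.position in cgs:
            pos = site.position
            fwd = True
        elif site.strand == "-" and (site.position - 1) in cgs:
            pos = site.position - 1
            fwd = False
        else:
            n_excluded += 1  # non-CG cytosine (read error or non-CpG context)
            continue
        key = (site.contig, pos)
        cpg = acc.get(key)
        if cpg is None:
            cpg = acc[key] = CpGSite(site.contig, pos)
        cpg.n_modified += site.n_modified
        cpg.n_canonical += site.n_canonical
        if fwd:
            cpg.forward_coverage += site.valid_coverage
        else:
            cpg.reverse_coverage += site.valid_coverage
    if n_excluded:
        logger.debug("collapse_cpg: excluded %d strand sites not at a reference CG",
                     n_excluded)
    return [acc[k] for k in sorted(acc)]


def covered_cpg_fraction(
    cpgs: Iterable[CpGSite],
    ref: Mapping[str, GenomeSequence] | Sequence[GenomeSequence],
    contigs: Sequence[str] | None = None,
) -> tuple[dict[str, float], float]:
    """Fraction of reference CpG sites covered on *both* strands.

    Numerator: CpG sites with forward and reverse coverage >= 1 each;
    denominator: all CG dinucleotides of the selected contigs. Returns
    (per-contig fractions, overall fraction).
    """
    ref_map = (
        dict(ref) if isinstance(ref, Mapping) else {c.name: c for c in ref}
    )
    names = list(contigs) if contigs is not None else list(ref_map)
    if not names:
        raise ValueError("empty contig set")
    denom = {name: len(cpg_positions(ref_map[name])) for name in names}
    numer: dict[str, int] = defaultdict(int)
    for cpg in cpgs:
        if cpg.contig in denom and cpg.forward_coverage >= 1 and cpg.reverse_coverage >= 1:
            numer[cpg.contig] += 1
    per_contig = {
        name: (numer[name] / denom[name]) if denom[name] else 0.0 for name in names
    }
    total_d = sum(denom.values())
    overall = (sum(numer[name] for name in names) / total_d) if total_d else 0.0
    return per_contig, overall


def bin_methylation(
    cpgs: Iterable[CpGSite],
    ref: Mapping[str, GenomeSequence] | Sequence[GenomeSequence],
    bin_size: int = 100_000,
) -> list[RegionMethylation]:
    """Tile each contig into fixed bins and pool CpG counts per bin.

    Bins with zero valid calls are emitted with an absent proportion so the
    tiling is complete; the last bin truncates at the contig end.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    ref_map = dict(ref) if isinstance(ref, Mapping) else {c.name: c for c in ref}
    pooled: dict[tuple[str, int], list[int]] = defaultdict(lambda: [0, 0, 0])
    for cpg in cpgs:
        key = (cpg.contig, cpg.position // bin_size)
        entry = pooled[key]
        entry[0] += cpg.n_modified
        entry[1] += cpg.valid_coverage
        entry[2] += 1
    out: list[RegionMethylation] = []
    for name, contig in ref_map.items():
        n_bins = (contig.length + bin_size - 1) // bin_size
        for b in range(n_bins):
            mod, valid, n_sites = pooled.get((name, b), (0, 0, 0))
            out.append(
                RegionMethylation(
                    interval=GenomicInterval(
                        name, b * bin_size, min((b + 1) * bin_size, contig.length)
                    ),
                    n_modified=mod,
                    n_valid=valid,
                    n_sites=n_sites,
                )
            )
    return out


def promoter_methylation(
    cpgs: Iterable[CpGSite],
    tss: Sequence[GenomicInterval],
    ref: Mapping[str, GenomeSequence] | Sequence[GenomeSequence],
    upstream: int = 5000,
) -> list[RegionMethylation]:
    """Pool CpG counts over the strand-aware upstream window of each TSS.

    The promoter is [TSS-upstream, TSS) for + genes and (TSS, TSS+upstream]
    for - genes, clipped to contig bounds; one record per gene. For interval
    records the TSS is the strand-appropriate boundary (start for +, end-1
    for -). Records whose TSS lies outside the contig are skipped.
    """
    ref_map = dict(ref) if isinstance(ref, Mapping) else {c.name: c for c in ref}
    by_contig: dict[str, list[CpGSite]] = defaultdict(list)
    for cpg in cpgs:
        by_contig[cpg.contig].append(cpg)
    for sites in by_contig.values():
        sites.sort(key=lambda s: s.position)
    positions = {
        name: np.array([s.position for s in sites])
        for name, sites in by_contig.items()
    }
    out: list[RegionMethylation] = []
    for rec in tss:
        contig = ref_map.get(rec.contig)
        if contig is None:
            continue
        if rec.strand == "-":
            t = rec.end - 1
            start, end = t + 1, t + 1 + upstream
        else:
            t = rec.start
            start, end = t - upstream, t
        if not 0 <= t < contig.length:
            logger.warning("promoter_methylation: TSS of %s outside contig %s, skipped",
                           rec.name, rec.contig)
            continue
        start = max(start, 0)
        end = min(end, contig.length)
        mod = valid = n_sites = 0
        contig_sites = by_contig.get(rec.contig, [])
        pos = positions.get(rec.contig)
        if pos is not None and pos.size:
            lo, hi = np.searchsorted(pos, [start, end])
            for s in contig_sites[lo:hi]:
                mod += s.n_modified
                valid += s.valid_coverage
                n_sites += 1
        out.append(
            RegionMethylation(
                interval=GenomicInterval(rec.contig, start, end, rec.strand, rec.name),
                n_modified=mod,
                n_valid=valid,
                n_sites=n_sites,
            )
        )
    return out


def per_read_methylation(
    read: AlignedModRead, threshold: float = 0.5, lower: float | None = None
) -> float | None:
    """Fraction of a read's unambiguous calls that are modified (None if none)."""
    mod = canon = 0
    for call in read.mod_calls:
        kind = classify_call(call.probability, threshold, lower)
        if kind == "modified":
            mod += 1
        elif kind == "canonical":
            canon += 1
    if mod + canon == 0:
        return None
    return mod / (mod + canon)


def overall_methylation(sites: Iterable[SiteMethylation | CpGSite]) -> float:
    """Genome-wide percent methylated: pooled modified / valid over all sites."""
    mod = valid = 0
    for site in sites:
        mod += site.n_modified
        valid += site.valid_coverage
    if valid == 0:
        raise ValueError("no valid calls: overall methylation undefined")
    return 100.0 * mod / valid


def write_regions_tsv(regions: Sequence[RegionMethylation], path) -> None:
    """Region table: contig, start, end, name, n_modified, n_valid, n_sites, pct."""
    with open(path, "w") as fh:
        fh.write("contig\tstart\tend\tname\tn_modified\tn_valid\tn_sites\tpct\n")
        for r in regions:
            pct = "NA" if r.proportion is None else format(r.proportion, ".6g")
            fh.write(
                f"{r.interval.contig}\t{r.interval.start}\t{r.interval.end}\t"
                f"{r.interval.name}\t{r.n_modified}\t{r.n_valid}\t{r.n_sites}\t{pct}\n"
            )


def read_regions_tsv(path) -> list[RegionMethylation]:
    out: list[RegionMethylation] = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("contig\t"):
            raise ValueError(f"{path}: missing region TSV header")
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            out.append(
                RegionMethylation(
                    interval=GenomicInterval(
                        fields[0], int(fields[1]), int(fields[2]), name=fields[3]
                    ),
                    n_modified=int(fields[4]),
                    n_valid=int(fields[5]),
                    n_sites=int(fields[6]),
                )
            )
    return out


def bedmethyl_to_cpgs(records: Iterable[BedMethylRecord]) -> list[CpGSite]:
    """Reconstruct collapsed CpG sites from strand-'.' bedMethyl records."""
    out = []
    for r in records:
        mod = int(round(r.percent_methylated / 100.0 * r.coverage))
        out.append(
            CpGSite(
                contig=r.contig,
                position=r.start,
                n_modified=mod,
                n_canonical=r.coverage - mod,
                forward_coverage=r.coverage,
                reverse_coverage=r.coverage,
            )
        )
    return out


def sites_to_bedmethyl(sites: Sequence[SiteMethylation]) -> list[BedMethylRecord]:
    return [
        BedMethylRecord(
            contig=s.contig,
            start=s.position,
            strand=s.strand,
            coverage=s.valid_coverage,
            percent_methylated=100.0 * (s.proportion or 0.0),
        )
        for s in sorted(sites, key=lambda s: (s.contig, s.position, s.strand))
        if s.valid_coverage > 0
    ]


def cpgs_to_bedmethyl(cpgs: Sequence[CpGSite]) -> list[BedMethylRecord]:
    return [
        BedMethylRecord(
            contig=c.contig,
            start=c.position,
            strand=".",
            coverage=c.valid_coverage,
            percent_methylated=100.0 * (c.proportion or 0.0),
        )
        for c in sorted(cpgs, key=lambda c: (c.contig, c.position))
        if c.valid_coverage > 0
    ]
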