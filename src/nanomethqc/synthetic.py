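"""Synthetic study data with known ground truth.

Generates a toy genome with a controlled GC landscape and CpG density, a
bimodal ground-truth methylome, ONT-like aligned reads carrying per-base
qualities and per-cytosine 5mC probability calls, WGBS-like per-site tables
with a tunable GC-dependent depth bias, and chain files describing edits
between two assembly versions.

The genome generator suppresses background CG dinucleotides and plants CGs
at the configured density, mimicking the CpG depletion of vertebrate
genomes so that site density is an experimental dial rather than an
accident of base composition. Per-read methylation is single-molecule:
each read draws a Bernoulli state from the site's true methylation level,
and the emitted call probability lands on the correct side of 0.5 with the
configured fidelity.

All generators are deterministic given the configuration seed; each stage
uses an independent seeded stream so regenerating one output never
perturbs another.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .core_io import (
    AlignedModRead,
    BedMethylRecord,
    ChainAlignment,
    ChainBlock,
    FastqRead,
    GenomeSequence,
    GenomicInterval,
    ModCall,
    revcomp,
)

__all__ = [
    "SimulationConfig",
    "TruthTable",
    "simulate_genome",
    "simulate_methylome",
    "simulate_ont_reads",
    "simulate_wgbs_sites",
    "simulate_chain",
    "simulate_tss",
    "simulate_raw_fastq",
    "reads_to_fastq",
    "write_truth_tsv",
    "read_truth_tsv",
]

_A, _C, _G, _T, _N = (ord(b) for b in "ACGTN")
_BASES = np.array([_A, _C, _G, _T], dtype=np.uint8)

# independent RNG stream tags per generator stage
_STREAM_GENOME, _STREAM_METHYLOME, _STREAM_READS, _STREAM_WGBS, _STREAM_MISC = range(5)


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic dataset.

    Defaults describe a desk-scale analogue of a nanopore methylation run:
    two 250 kb contigs (~10 CpG/kb, so ~5,000 CpG sites), a Beta-mixture
    methylome with mean ~0.78 (hypermethylated bulk plus a hypomethylated
    minority, the bimodal genome-wide pattern of vertebrate methylomes),
    2,000 reads of mean length 5 kb (~20x coverage) with 5% per-base error
    (~95% read accuracy), and WGBS coverage of 15x with a log2-linear GC
    depth bias giving 2x depth at 20% GC and 0.5x at 60% GC.
    """

    seed: int = 0
    n_contigs: int = 2
    contig_length: int = 250_000
    gc_window: int = 1000
    # per-window GC targets, cycled along each contig
    gc_landscape: tuple[float, ...] = tuple(np.round(np.linspace(0.25, 0.55, 25), 3))
    cpg_per_kb: float = 10.0
    # Beta mixture for true per-site methylation: (weight, alpha, beta)
    methylome_mixture: tuple[tuple[float, float, float], ...] = (
        (0.85, 12.0, 1.5),
        (0.15, 1.5, 10.0),
    )
    n_reads: int = 2000
    mean_read_length: int = 5000
    min_read_length: int = 300
    error_rate: float = 0.05
    # split of error_rate into substitution / insertion / deletion
    error_mix: tuple[float, float, float] = (0.6, 0.2, 0.2)
    call_fidelity: float = 0.95
    wgbs_mean_depth: float = 15.0
    wgbs_gc_log2_slope: float = -0.05  # log2 depth factor per GC percentage point
    wgbs_gc_center: float = 40.0

    def __post_init__(self) -> None:
        if self.n_contigs <= 0 or self.contig_length <= 0 or self.n_reads <= 0:
            raise ValueError("counts and lengths must be positive")
        for p in (self.error_rate, self.call_fidelity):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if not math.isclose(sum(self.error_mix), 1.0):
            raise ValueError("error_mix must sum to 1")
        if not math.isclose(sum(w for w, _, _ in self.methylome_mixture), 1.0):
            raise ValueError("methylome mixture weights must sum to 1")

    def gc_depth_factor(self, gc_percent: float) -> float:
        """Multiplicative WGBS depth factor injected for a bin's GC percent."""
        return 2.0 ** (self.wgbs_gc_log2_slope * (gc_percent - self.wgbs_gc_center))

    def mixture_mean(self) -> float:
        return sum(w * a / (a + b) for w, a, b in self.methylome_mixture)


@dataclass
class TruthTable:
    """Ground truth behind a simulated dataset."""

    cpg_positions: dict[str, np.ndarray] = field(default_factory=dict)
    p: dict[str, np.ndarray] = field(default_factory=dict)  # true methylation per CpG
    read_origins: dict[str, GenomicInterval] = field(default_factory=dict)

    def mean_methylation(self) -> float:
        all_p = np.concatenate([self.p[c] for c in sorted(self.p)])
        return float(all_p.mean())

    def n_sites(self) -> int:
        return sum(len(v) for v in self.cpg_positions.values())

    def site_index(self) -> dict[tuple[str, int], float]:
        return {
            (contig, int(pos)): float(pi)
            for contig in sorted(self.cpg_positions)
            for pos, pi in zip(self.cpg_positions[contig], self.p[contig])
        }


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stream])


# ---------------------------------------------------------------------------
# Genome
# ---------------------------------------------------------------------------

def simulate_genome(config: SimulationConfig) -> tuple[list[GenomeSequence], TruthTable]:
    """Build the toy genome and the CpG-position skeleton of the truth table.

    Each 1 kb window realizes its target GC within 2 percentage points; CG
    dinucleotides occur only where planted (plus none elsewhere), at an
    expected density of ``cpg_per_kb``.
    """
    rng = _rng(config, _STREAM_GENOME)
    contigs: list[GenomeSequence] = []
    truth = TruthTable()
    for ci in range(config.n_contigs):
        name = f"contig{ci + 1}"
        windows = []
        n_windows = (config.contig_length + config.gc_window - 1) // config.gc_window
        for wi in range(n_windows):
            length = min(config.gc_window, config.contig_length - wi * config.gc_window)
            target = config.gc_landscape[wi % len(config.gc_landscape)]
            windows.append(_build_window(rng, length, target, config.cpg_per_kb))
        arr = np.concatenate(windows)
        _fix_boundary_cg(arr, config.gc_window)
        seq = arr.tobytes().decode()
        contigs.append(GenomeSequence(name, seq))
        sarr = np.frombuffer(seq.encode(), dtype=np.uint8)
        truth.cpg_positions[name] = np.flatnonzero(
            (sarr[:-1] == _C) & (sarr[1:] == _G)
        )
    return contigs, truth


def _build_window(
    rng: np.random.Generator, length: int, gc_target: float, cpg_per_kb: float
) -> np.ndarray:
    n_gc = int(round(gc_target * length))
    arr = np.concatenate(
        [
            np.full(n_gc // 2, _G, dtype=np.uint8),
            np.full(n_gc - n_gc // 2, _C, dtype=np.uint8),
            np.full((length - n_gc) // 2, _A, dtype=np.uint8),
            np.full(length - n_gc - (length - n_gc) // 2, _T, dtype=np.uint8),
        ]
    )
    rng.shuffle(arr)
    _remove_cg(rng, arr)
    planted = _plant_cpgs(rng, arr, cpg_per_kb)
    protected = set(planted) | {p + 1 for p in planted}
    _fix_gc(rng, arr, n_gc, protected)
    return arr


def _remove_cg(rng: np.random.Generator, arr: np.ndarray) -> None:
    """Eliminate CG dinucleotides by swapping the G with a safe A/T position."""
    for _ in range(200):
        cg = np.flatnonzero((arr[:-1] == _C) & (arr[1:] == _G))
        if cg.size == 0:
            return
        at = np.flatnonzero((arr == _A) | (arr == _T))
        if at.size == 0:
            break
        for i in cg:
            if arr[i] != _C or arr[i + 1] != _G:
                continue  # already fixed by a previous swap
            for j in rng.permutation(at)[:30]:
                # placing G at j is safe unless a C precedes it
                if j in (i, i + 1) or (j > 0 and arr[j - 1] == _C) or arr[j] not in (_A, _T):
                    continue
                arr[i + 1], arr[j] = arr[j], _G
                break
    # pathological compositions may leave stray CGs; neutralize the G
    cg = np.flatnonzero((arr[:-1] == _C) & (arr[1:] == _G))
    arr[cg + 1] = _A


def _plant_cpgs(
    rng: np.random.Generator, arr: np.ndarray, cpg_per_kb: float
) -> list[int]:
    length = arr.size
    n_plant = rng.poisson(cpg_per_kb * length / 1000.0)
    if n_plant == 0 or length < 2:
        return []
    candidates = rng.permutation(length - 1)
    planted: list[int] = []
    occupied: set[int] = set()
    for p in candidates:
        if len(planted) == n_plant:
            break
        if p in occupied or (p + 1) in occupied or (p - 1) in occupied:
            continue
        planted.append(int(p))
        occupied.update((p, p + 1))
    for p in planted:
        arr[p] = _C
        arr[p + 1] = _G
    return planted


def _fix_gc(
    rng: np.random.Generator,
    arr: np.ndarray,
    target_count: int,
    protected: set[int],
) -> None:
    """Flip safe bases until the window's GC count is within 0.5 pp of target."""
    tol = max(1, int(round(arr.size * 0.005)))
    for _ in range(300):
        current = int(np.count_nonzero((arr == _G) | (arr == _C)))
        diff = current - target_count
        if abs(diff) <= tol:
            return
        if diff > 0:
            # demote a G/C that is not protected and not part of a CG pair
            cand = [
                i
                for i in rng.permutation(arr.size)[:200]
                if i not in protected
                and (
                    (arr[i] == _C and (i + 1 >= arr.size or arr[i + 1] != _G))
                    or (arr[i] == _G and (i == 0 or arr[i - 1] != _C))
                )
            ]
            if not cand:
                return
            arr[cand[0]] = _A if rng.random() < 0.5 else _T
        else:
            cand = None
            for i in rng.permutation(arr.size)[:200]:
                if i in protected or arr[i] not in (_A, _T):
                    continue
                if i + 1 >= arr.size or arr[i + 1] != _G:
                    cand = (i, _C)  # C is safe: no G follows
                    break
                if i == 0 or arr[i - 1] != _C:
                    cand = (i, _G)  # G is safe: no C precedes
                    break
            if cand is None:
                return
            arr[cand[0]] = cand[1]


def _fix_boundary_cg(arr: np.ndarray, window: int) -> None:
    for b in range(window, arr.size, window):
        if arr[b - 1] == _C and arr[b] == _G:
            arr[b] = _A


# ---------------------------------------------------------------------------
# Methylome
# ---------------------------------------------------------------------------

def simulate_methylome(
    genomes: Sequence[GenomeSequence], config: SimulationConfig, truth: TruthTable
) -> TruthTable:
    """Draw the true per-CpG methylation level from the configured Beta mixture."""
    rng = _rng(config, _STREAM_METHYLOME)
    weights = np.array([w for w, _, _ in config.methylome_mixture])
    for genome in genomes:
        positions = truth.cpg_positions.get(genome.name)
        if positions is None:
            raise ValueError(f"truth table lacks CpG positions for {genome.name!r}")
        comp = rng.choice(len(weights), size=positions.size, p=weights)
        p = np.empty(positions.size)
        for k, (_w, a, b) in enumerate(config.methylome_mixture):
            mask = comp == k
            p[mask] = rng.beta(a, b, size=int(mask.sum()))
        truth.p[genome.name] = p
    return truth


# ---------------------------------------------------------------------------
# ONT-like reads
# ---------------------------------------------------------------------------

def _quality_mixture(error_rate: float) -> tuple[int, int, float]:
    """Two adjacent Phred values whose mixture mean error equals error_rate."""
    if error_rate <= 0:
        return 60, 60, 1.0
    q_exact = -10.0 * math.log10(error_rate)
    qlo = int(math.floor(q_exact))
    qhi = qlo + 1
    elo, ehi = 10.0 ** (-qlo / 10.0), 10.0 ** (-qhi / 10.0)
    w_hi = (elo - error_rate) / (elo - ehi)
    return qlo, qhi, w_hi


def simulate_ont_reads(
    genomes: Sequence[GenomeSequence],
    truth: TruthTable,
    config: SimulationConfig,
) -> list[AlignedModRead]:
    """Simulate aligned nanopore-like reads with 5mC probability calls.

    Reads are placed uniformly over the genome, strands balanced. Per-base
    errors (substitution/insertion/deletion at the configured mix) are
    encoded in the CIGAR and sequence; qualities are drawn so their mean
    error probability equals the injected error rate. Every intact read
    cytosine over a true CpG receives a modification call whose probability
    falls on the correct side of 0.5 with probability ``call_fidelity``
    given the molecule's Bernoulli(p_i) state.
    """
    rng = _rng(config, _STREAM_READS)
    e = config.error_rate
    p_sub, p_ins, p_del = (m * e for m in config.error_mix)
    qlo, qhi, w_hi = _quality_mixture(e)
    lengths = np.array([g.length for g in genomes], dtype=float)
    contig_prob = lengths / lengths.sum()
    seqs = {g.name: np.frombuffer(g.sequence.encode(), dtype=np.uint8) for g in genomes}

    reads: list[AlignedModRead] = []
    for k in range(config.n_reads):
        gi = rng.choice(len(genomes), p=contig_prob)
        genome = genomes[gi]
        clen = genome.length
        rl = int(rng.gamma(2.0, config.mean_read_length / 2.0))
        rl = max(config.min_read_length, min(rl, clen))
        start = int(rng.integers(0, clen - rl + 1))
        ref = seqs[genome.name][start : start + rl]

        u = rng.random(rl)
        del_mask = u < p_del
        sub_mask = (u >= p_del) & (u < p_del + p_sub)
        qbase = ref.copy()
        subs = np.flatnonzero(sub_mask)
        if subs.size:
            # shift by 1-3 in base order => always a different base
            shift = rng.integers(1, 4, size=subs.size)
            idx = np.searchsorted(_BASES, ref[subs])
            qbase[subs] = _BASES[(idx + shift) % 4]
        ops = np.where(del_mask, np.uint8(ord("D")), np.uint8(ord("M")))
        ins_idx = np.flatnonzero(rng.random(rl) < p_ins)
        if ins_idx.size:
            ins_bases = _BASES[rng.integers(0, 4, size=ins_idx.size)]
            final_ops = np.insert(ops, ins_idx + 1, ord("I"))
            final_q = np.insert(qbase, ins_idx + 1, ins_bases)
        else:
            final_ops, final_q = ops, qbase
        keep = final_ops != ord("D")
        query = final_q[keep]
        q_indices = np.cumsum(keep) - 1
        r_indices = np.cumsum(final_ops != ord("I")) - 1
        ref_to_q = np.full(rl, -1, dtype=np.int64)
        m_pos = np.flatnonzero(final_ops == ord("M"))
        ref_to_q[r_indices[m_pos]] = q_indices[m_pos]

        strand = "+" if rng.random() < 0.5 else "-"
        lq = int(query.size)
        cpos = truth.cpg_positions[genome.name]
        p_true = truth.p[genome.name]
        lo, hi = np.searchsorted(cpos, [start, start + rl])
        calls: list[ModCall] = []
        for cp, pi in zip(cpos[lo:hi], p_true[lo:hi]):
            if strand == "+":
                ro = int(cp) - start
                expected = _C
            else:
                ro = int(cp) + 1 - start  # the G carries the reverse-strand C
                expected = _G
                if ro >= rl:
                    continue
            q = int(ref_to_q[ro])
            if q < 0 or query[q] != expected:
                continue  # base deleted or miscalled: no modification call
            offset = q if strand == "+" else lq - 1 - q
            state = rng.random() < pi
            called_mod = state if rng.random() < config.call_fidelity else not state
            prob = rng.uniform(0.5, 1.0) if called_mod else rng.uniform(0.0, 0.5)
            calls.append(ModCall(int(offset), float(prob)))
        calls.sort()
        quals = np.where(rng.random(lq) < w_hi, qhi, qlo).astype(int)
        read = AlignedModRead(
            read_id=f"read{k:06d}",
            contig=genome.name,
            ref_start=start,
            strand=strand,
            cigar=_rle_cigar(final_ops),
            sequence=query.tobytes().decode(),
            qualities=quals.tolist(),
            mod_calls=calls,
        )
        reads.append(read)
        truth.read_origins[read.read_id] = GenomicInterval(
            genome.name, start, start + rl, strand
        )
    return reads


def _rle_cigar(ops: np.ndarray) -> list[tuple[str, int]]:
    if ops.size == 0:
        return []
    change = np.flatnonzero(np.diff(ops)) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [ops.size]])
    return [(chr(ops[s]), int(e - s)) for s, e in zip(starts, ends)]


def reads_to_fastq(reads: Sequence[AlignedModRead]) -> list[FastqRead]:
    """Reads in original (basecall) orientation, as they would leave the sequencer."""
    out = []
    for read in reads:
        if read.strand == "-":
            out.append(
                FastqRead(read.read_id, revcomp(read.sequence), read.qualities[::-1])
            )
        else:
            out.append(FastqRead(read.read_id, read.sequence, list(read.qualities)))
    return out


def simulate_raw_fastq(
    n_reads: int,
    seed: int,
    length_range: tuple[int, int] = (80, 2000),
    q_range: tuple[int, int] = (3, 30),
) -> list[FastqRead]:
    """Unfiltered FASTQ-style reads with a spread of lengths and qualities.

    Lengths straddle the trimming/length thresholds and read-level qualities
    straddle the Q7 cutoff, so a filtering pass exercises every rejection
    reason.
    """
    rng = np.random.default_rng(seed)
    reads = []
    for k in range(n_reads):
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        seq = _BASES[rng.integers(0, 4, size=length)].tobytes().decode()
        q_center = int(rng.integers(q_range[0], q_range[1] + 1))
        quals = np.clip(
            rng.normal(q_center, 2.0, size=length).round().astype(int), 1, 50
        )
        reads.append(FastqRead(f"raw{k:05d}", seq, quals.tolist()))
    return reads


# ---------------------------------------------------------------------------
# WGBS-like site tables
# ---------------------------------------------------------------------------

def simulate_wgbs_sites(
    genomes: Sequence[GenomeSequence],
    truth: TruthTable,
    config: SimulationConfig,
    depth_bin: int = 1000,
) -> tuple[list[BedMethylRecord], list[tuple[str, int, int, float]]]:
    """Per-CpG bisulfite-style records plus a per-bin depth table.

    Site coverage is Poisson with mean ``wgbs_mean_depth`` multiplied by the
    injected GC-depth factor of the containing bin; methylated counts are
    Binomial(coverage, p_i). Zero-coverage sites are omitted, reproducing
    the CpG recovery gap of GC-biased short-read data.
    """
    rng = _rng(config, _STREAM_WGBS)
    records: list[BedMethylRecord] = []
    depth_rows: list[tuple[str, int, int, float]] = []
    for genome in genomes:
        seq = np.frombuffer(genome.sequence.encode(), dtype=np.uint8)
        n_bins = (genome.length + depth_bin - 1) // depth_bin
        factors = np.empty(n_bins)
        for b in range(n_bins):
            start, end = b * depth_bin, min((b + 1) * depth_bin, genome.length)
            window = seq[start:end]
            informative = np.count_nonzero(window != _N)
            gc = (
                100.0 * np.count_nonzero((window == _G) | (window == _C)) / informative
                if informative
                else 0.0
            )
            factors[b] = config.gc_depth_factor(round(gc))
            total_depth = rng.poisson(config.wgbs_mean_depth * factors[b] * (end - start))
            depth_rows.append((genome.name, start, end, float(total_depth)))
        positions = truth.cpg_positions[genome.name]
        p_true = truth.p[genome.name]
        site_mean = config.wgbs_mean_depth * factors[positions // depth_bin]
        coverage = rng.poisson(site_mean)
        methylated = rng.binomial(coverage, p_true)
        for pos, cov, k in zip(positions, coverage, methylated):
            if cov == 0:
                continue
            records.append(
                BedMethylRecord(
                    contig=genome.name,
                    start=int(pos),
                    strand=".",
                    coverage=int(cov),
                    percent_methylated=100.0 * k / cov,
                )
            )
    return records, depth_rows


def write_truth_tsv(truth: TruthTable, path) -> None:
    """Ground-truth methylome table: contig, CpG position, true p."""
    with open(path, "w") as fh:
        fh.write("contig\tposition\tp\n")
        for contig in sorted(truth.cpg_positions):
            for pos, pi in zip(truth.cpg_positions[contig], truth.p[contig]):
                fh.write(f"{contig}\t{int(pos)}\t{pi:.8f}\n")


def read_truth_tsv(path) -> TruthTable:
    truth = TruthTable()
    pos: dict[str, list[int]] = {}
    p: dict[str, list[float]] = {}
    with open(path) as fh:
        fh.readline()
        for line in fh:
            contig, position, pi = line.rstrip("\n").split("\t")
            pos.setdefault(contig, []).append(int(position))
            p.setdefault(contig, []).append(float(pi))
    truth.cpg_positions = {c: np.array(v) for c, v in pos.items()}
    truth.p = {c: np.array(v) for c, v in p.items()}
    return truth


# ---------------------------------------------------------------------------
# Annotations and assembly edits
# ---------------------------------------------------------------------------

def simulate_tss(
    genomes: Sequence[GenomeSequence],
    config: SimulationConfig,
    n_genes: int = 50,
    upstream: int = 5000,
) -> list[GenomicInterval]:
    """Random single-base TSS records (BED6-style), strands balanced."""
    rng = _rng(config, _STREAM_MISC)
    out = []
    for gi, genome in enumerate(genomes):
        for k in range(n_genes):
            t = int(rng.integers(upstream, genome.length - upstream))
            strand = "+" if rng.random() < 0.5 else "-"
            out.append(
                GenomicInterval(genome.name, t, t + 1, strand, f"gene{gi}_{k:03d}")
            )
    return out


def simulate_chain(
    genomes: Sequence[GenomeSequence],
    edits: Sequence[tuple[str, str, int, int]],
    seed: int = 0,
) -> tuple[list[GenomeSequence], list[ChainAlignment]]:
    """Apply an edit script to an assembly and emit the exact chains.

    ``edits`` rows are (contig, op, source position, length) with op in
    {'insertion', 'deletion'}; edits must be non-overlapping, strictly
    ordered and leave non-empty aligned blocks between them. An empty
    script yields identity chains.
    """
    rng = np.random.default_rng(seed)
    by_contig: dict[str, list[tuple[str, int, int]]] = {}
    for contig, op, pos, length in edits:
        if op not in ("insertion", "deletion"):
            raise ValueError(f"unknown edit op {op!r}")
        if length <= 0:
            raise ValueError("edit length must be positive")
        by_contig.setdefault(contig, []).append((op, pos, length))

    new_genomes: list[GenomeSequence] = []
    chains: list[ChainAlignment] = []
    for genome in genomes:
        contig_edits = sorted(by_contig.get(genome.name, []), key=lambda e: e[1])
        cursor = 0
        parts: list[str] = []
        blocks: list[ChainBlock] = []
        for op, pos, length in contig_edits:
            end = pos + length if op == "deletion" else pos
            if pos <= cursor or end >= genome.length:
                raise ValueError(
                    f"edits on {genome.name} overlap or touch contig bounds near {pos}"
                )
            size = pos - cursor
            parts.append(genome.sequence[cursor:pos])
            if op == "deletion":
                blocks.append(ChainBlock(size, length, 0))
                cursor = pos + length
            else:
                ins = _BASES[rng.integers(0, 4, size=length)].tobytes().decode()
                parts.append(ins)
                blocks.append(ChainBlock(size, 0, length))
                cursor = pos
        parts.append(genome.sequence[cursor:])
        blocks.append(ChainBlock(genome.length - cursor, 0, 0))
        target_seq = "".join(parts)
        new_genomes.append(GenomeSequence(genome.name, target_seq))
        chains.append(
            ChainAlignment(
                score=float(genome.length),
                source_name=genome.name,
                source_size=genome.length,
                source_strand="+",
                source_start=0,
                source_end=genome.length,
                target_name=genome.name,
                target_size=len(target_seq),
                target_strand="+",
                target_start=0,
                target_end=len(target_seq),
                blocks=tuple(blocks),
                chain_id=str(len(chains) + 1),
            )
        )
    return new_genomes, chains
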