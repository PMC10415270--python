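# Methods

## Scope and model

The package validates a 5mC methylation-calling workflow for nanopore
long reads. Its unit of observation is an aligned read carrying
per-cytosine modification probabilities (MM/ML tags); its central derived
objects are the per-strand site pileup, the strand-collapsed CpG site and
the pooled regional proportion. Everything is exercised end-to-end on
synthetic data whose ground truth is known, so each statistic can be
checked for parameter recovery rather than merely for plausibility.

## Read accuracy and filtering

Estimated accuracy converts Phred qualities to error probabilities and
averages them: 1 − (1/N)·Σ 10^(−qᵢ/10). Observed accuracy counts
alignment events with N(total) = N(sub) + N(mat) + N(ins) + N(del); `M`
CIGAR operations are split into match/substitution by comparison with the
reference (MD tags are not required — the reference is always at hand
here), `=`/`X` count directly, and soft/hard clips and reference skips
contribute to no term. Columns whose reference base is N are excluded
from both match and substitution counts, since no comparison is possible.

Filtering trims 50 bp from both ends first (qualities with the
sequence), then drops reads shorter than 200 bp or with read-level
quality below Q7, where read-level quality is −10·log₁₀ of the mean
per-base error probability — the Q-scale twin of estimated accuracy and
the convention of common long-read filters. Reads of ≤100 bp are
"fully trimmed" and logged under that reason.

Distribution summaries use a fixed-width histogram over [0, 1]
(default bin 0.005, i.e. half a percentage point); the mode is the center
of the maximal-count bin with ties broken toward the lower bin. The
normalized bin weights sum to 1.

## Pileup, thresholds and CpG collapsing

Modification calls are projected through the CIGAR to reference
coordinates; calls on inserted or clipped bases are dropped. A call with
probability ≥ t counts as modified and < 1 − t as canonical, with the
single threshold t = 0.5 by default, so no call is ambiguous and the
boundary p = 0.5 deterministically classifies as modified. A
dual-threshold mode (e.g. 0.33/0.66) discards mid-probability calls,
emulating tools that ignore low-confidence calls; counts discarded this
way are kept separately as ambiguous.

CpG identity is defined on the reference: a site is a CG dinucleotide of
the forward strand, and the reverse-strand C is the G at the following
position. Collapsing pools the two strand sites' modified/canonical
counts and records forward and reverse coverage separately, so the
covered-CpG criterion — at least one read on each strand — can be
evaluated per site. Defining CpGs on the reference (not on reads)
prevents sequencing errors from creating phantom sites; strand sites that
do not sit at a reference CG are excluded from collapsing and logged.

## Regional methylation

Regions are 100 kb tiles of each contig (last tile truncated) and 5 kb
promoter windows: [TSS − 5000, TSS) for + genes and (TSS, TSS + 5000]
for − genes, clipped to contig bounds. Upstream is resolved
strand-specifically because it is undefined otherwise; overlapping genes
each get their own record, without merging. The regional proportion is
the coverage-weighted pooled ratio 100·Σ modified / Σ valid rather than
the unweighted mean of site proportions; pooling is the only choice under
which bins aggregate exactly to the genome-wide figure, a property the
tests assert to 1e−12.

## Subsampling, correlation, GC bias and liftover

Subsampling keeps each read independently with probability equal to the
requested proportion (Bernoulli, not exact-count), so proportion 1.0
reproduces the full dataset exactly and curves are deterministic given
the base seed; per-replicate seeds are drawn once from the base seed and
recorded in the curve object. The proportion grid defaults to
0.1…1.0 in tens with 10 replicates; 0 % is excluded as degenerate.
Genome recovery counts reference bases covered by ≥1 aligned base, with
deletions covering (the read spans them) and insertions/clips not.

Regional Pearson correlation uses complete cases (regions with data in
both sets). The shared-site variant recomputes each dataset's regional
proportions using only CpG positions with data in both datasets before
correlating, so platform coverage differences cannot drive the result;
intersecting region lists without recomputation would be the cheaper but
weaker alternative.

GC-bias profiles assign each 1 kb bin an integer GC percent computed
over its non-N bases (bins more than half N are dropped, avoiding
spurious 0 %-GC levels from assembly gaps), average coverage per GC
level, and normalize by the unweighted mean of the per-level means whose
GC lies in the 10–60 % range — the range that contains the bulk of a
vertebrate genome's bins. A flat profile is identically 1.

Liftover maps single-base records through chain alignments by block
offset. Chains are validated at parse time (block arithmetic must match
the header spans). When several chains cover a position the
highest-score chain wins, and a position falling in that chain's gap is
unmapped — mirroring the reference liftover tool. Target-strand '−'
chains flip both the coordinate (size − 1 − pos) and the record strand.
Unmappable positions are results, not errors; mapped + unmapped always
equals the input count.

## Synthetic data: what it emulates and what it does not

The generator is the package's measurement standard, so its defaults are
fixed study conditions rather than tuning knobs:

- **Genome**: two contigs × 250 kb built in 1 kb windows whose GC targets
  ramp over 25–55 % (realized within 2 pp per window, giving the GC-bias
  profile a populated level range). Background CG dinucleotides are
  suppressed and CGs are planted at 10/kb (~5,000 sites), mimicking the
  CpG depletion of vertebrate genomes so density is controlled.
- **Methylome**: per-CpG true levels p_i from a two-component Beta
  mixture (weights 0.85/0.15, Beta(12, 1.5) hypermethylated and
  Beta(1.5, 10) hypomethylated), bimodal with mean ≈ 0.775 — the shape
  and level typical of a vertebrate somatic methylome.
- **Reads**: 2,000 reads, gamma-distributed lengths with mean 5 kb
  (~20× coverage), strands balanced, per-base error 5 % split
  0.6/0.2/0.2 into substitution/insertion/deletion and encoded in the
  CIGAR. Qualities are drawn from the two adjacent Phred values whose
  mixture mean error equals the injected rate, so estimated accuracy is
  unbiased. Methylation is single-molecule: each read draws a
  Bernoulli(p_i) state per covered CpG; with probability equal to the
  caller fidelity (default 0.95) the emitted probability is uniform on
  the correct side of 0.5, otherwise on the wrong side. Cytosines hit by
  a sequencing error receive no call, as a real caller would not see a C.
- **WGBS analogue**: per-CpG coverage Poisson with mean 15× multiplied
  by a log2-linear GC factor (slope −0.05 per GC point centered at 40 %,
  i.e. 2× depth at 20 % GC and 0.5× at 60 %); methylated counts
  Binomial(coverage, p_i); zero-coverage sites omitted. Bisulfite reads
  themselves are not simulated.
- **Assembly edits**: explicit insertion/deletion scripts produce a
  second assembly and the exactly corresponding chain file.

All stages draw from independent streams seeded from the single
configuration seed, so identical configurations yield byte-identical
files and regenerating one output never perturbs another.

Deliberate simplifications: errors are i.i.d. with no motif structure or
homopolymer effects; modification probabilities are uniform on each side
of 0.5 rather than basecaller-shaped; WGBS dropout is Poisson-only, so
the large covered-CpG gap real bisulfite data shows (driven additionally
by conversion damage and mappability) appears here only at low mean
depth; there is no 5hmC, no CRAM, and no haplotype structure. Passing
tests therefore demonstrate the correctness of the computations and
their statistical calibration under these conditions, not robustness to
real-world basecaller or library artifacts.

## Numerical choices and degenerate inputs

Probabilities decode from 256-bin ML values by the mid-bin rule
(ml + 0.5)/256, which never yields exactly 0 or 1 and round-trips through
encoding; quantization preserves the side of 0.5, so threshold decisions
survive a SAM round trip. Correlations require ≥3 pairs and nonzero
variance and raise otherwise. Empty quality vectors, empty tallies and
zero valid calls raise; an empty alignment set yields recovery 0.0 with
a warning. Secondary/supplementary alignments are parsed but excluded
from pileups and accuracy tallies unless explicitly included, since
per-read statistics need one record per read.

## Problem sizes

Tests run the generator at 30–50 kb contigs with a few hundred reads;
the end-to-end validation suite and the acceptance script use the full
default conditions (500 kb, 2,000 reads, ~94,000 CpG calls), where the
exact-binomial site-interval check and 3-SE genome-wide recovery bounds
are well powered. These sizes are the package's chosen desk-scale study
conditions; all statistics scale linearly in read count and genome size.
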