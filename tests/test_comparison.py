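"""Recovery, subsampling, correlation, GC bias and liftover."""

import numpy as np
import pytest

from nanomethqc.comparison import (
    gc_bias_profile,
    genome_recovery,
    liftover_sites,
    methylation_stability_curve,
    recovery_curve,
    region_correlation,
    shared_site_correlation,
    subsample_reads,
)
from nanomethqc.core_io import (
    AlignedModRead,
    BedMethylRecord,
    ChainAlignment,
    ChainBlock,
    GenomeSequence,
    GenomicInterval,
    invert_chain,
)
from nanomethqc.methylation import (
    CpGSite,
    RegionMethylation,
    collapse_cpg,
    overall_methylation,
    pileup_sites,
)


def span_read(contig, start, length, rid="r"):
    return AlignedModRead(
        rid, contig, start, "+", [("M", length)], "A" * length, [20] * length
    )


def walk_chain_positions(chain):
    """Block-walk oracle: explicit source->target map for every aligned base."""
    mapping = {}
    s, t = chain.source_start, chain.target_start
    for block in chain.blocks:
        for k in range(block.size):
            t_pos = t + k
            if chain.target_strand == "-":
                mapping[s + k] = chain.target_size - 1 - t_pos
            else:
                mapping[s + k] = t_pos
        s += block.size + block.dt
        t += block.size + block.dq
    return mapping


class TestGenomeRecovery:
    def test_full_span(self):
        ref = GenomeSequence("c", "A" * 100)
        assert genome_recovery([span_read("c", 0, 100)], ref) == 1.0

    def test_two_disjoint_reads(self):
        ref = GenomeSequence("c", "A" * 100)
        reads = [span_read("c", 0, 10, "a"), span_read("c", 50, 10, "b")]
        assert genome_recovery(reads, ref) == pytest.approx(0.2)

    def test_empty_set_is_zero(self):
        assert genome_recovery([], GenomeSequence("c", "ACGT")) == 0.0

    def test_deletions_cover_insertions_do_not(self):
        ref = GenomeSequence("c", "A" * 20)
        read = AlignedModRead(
            "r", "c", 0, "+", [("M", 5), ("D", 5), ("M", 2), ("I", 3)],
            "A" * 10, [20] * 10,
        )
        assert genome_recovery([read], ref) == pytest.approx(12 / 20)


class TestSubsampling:
    def test_full_proportion_is_identity(self, small_dataset):
        _, _, reads = small_dataset
        assert subsample_reads(reads, 1.0, seed=3) == reads

    def test_same_seed_same_subset(self, small_dataset):
        _, _, reads = small_dataset
        a = subsample_reads(reads, 0.4, seed=9)
        b = subsample_reads(reads, 0.4, seed=9)
        assert [r.read_id for r in a] == [r.read_id for r in b]

    def test_kept_count_within_binomial_bound(self, small_dataset):
        _, _, reads = small_dataset
        n = len(reads)
        kept = len(subsample_reads(reads, 0.5, seed=5))
        assert abs(kept - 0.5 * n) <= 3 * np.sqrt(n * 0.25)

    @pytest.mark.parametrize("bad", [0.0, -0.1, 1.5])
    def test_proportion_bounds(self, bad, small_dataset):
        _, _, reads = small_dataset
        with pytest.raises(ValueError):
            subsample_reads(reads, bad, seed=0)

    def test_recovery_curve_monotone_and_saturating(self, small_dataset, ref_map):
        _, _, reads = small_dataset
        grid = [0.2, 0.5, 0.8, 1.0]
        curve = recovery_curve(reads, ref_map, grid, replicates=4, base_seed=2)
        means = curve.means()
        assert all(b >= a - 1e-12 for a, b in zip(means, means[1:]))
        full = genome_recovery(reads, ref_map)
        assert all(v == pytest.approx(full) for v in curve.values[-1])

    def test_single_read_recovery_enumerates_outcomes(self):
        ref = GenomeSequence("c", "A" * 100)
        reads = [span_read("c", 0, 40)]
        curve = recovery_curve(reads, [ref], [0.5], replicates=20, base_seed=0)
        assert set(np.round(curve.values[0], 6)) <= {0.0, 0.4}

    def test_stability_curve_full_proportion_matches_pileup(
        self, small_dataset, ref_map
    ):
        _, _, reads = small_dataset
        curve = methylation_stability_curve(reads, [1.0], replicates=3, base_seed=7)
        cpg_free = overall_methylation(pileup_sites(reads, ref_map))
        assert all(v == pytest.approx(cpg_free, abs=1e-9) for v in curve.values[0])

    def test_stability_curve_all_modified(self):
        from nanomethqc.core_io import ModCall

        reads = [
            AlignedModRead(
                f"r{i}", "c", 0, "+", [("M", 4)], "CCCC", [20] * 4,
                [ModCall(j, 0.95) for j in range(4)],
            )
            for i in range(20)
        ]
        curve = methylation_stability_curve(reads, [0.3, 1.0], replicates=5, base_seed=1)
        for row in curve.values:
            for v in row:
                assert v is None or v == pytest.approx(100.0)


class TestRegionCorrelation:
    def _regions(self, values):
        return [
            RegionMethylation(
                GenomicInterval("c", i * 100, (i + 1) * 100),
                n_modified=int(v),
                n_valid=100,
                n_sites=1,
            )
            for i, v in enumerate(values)
        ]

    def test_identity_is_one(self):
        a = self._regions([10, 40, 70, 90])
        assert region_correlation(a, a).r == pytest.approx(1.0)

    def test_anticorrelated_is_minus_one(self):
        a = self._regions([10, 40, 70, 90])
        b = self._regions([90, 60, 30, 10])
        assert region_correlation(a, b).r == pytest.approx(-1.0)

    def test_few_pairs_rejected(self):
        a = self._regions([10, 20])
        with pytest.raises(ValueError):
            region_correlation(a, a)

    def test_latent_correlation_recovered(self, rng):
        """Bins built from a known bivariate normal: r within 3 Fisher-z SE."""
        rho, n = 0.7, 400
        cov = [[1, rho], [rho, 1]]
        xy = rng.multivariate_normal([50, 50], np.array(cov) * 100, size=n)
        xy = np.clip(xy, 0, 100)
        a = self._regions(xy[:, 0])
        b = self._regions(xy[:, 1])
        r = region_correlation(a, b).r
        se = 1 / np.sqrt(n - 3)
        assert abs(np.arctanh(r) - np.arctanh(rho)) < 3.5 * se

    def test_shared_site_restriction_aligns_datasets(self):
        ref = GenomeSequence("c", "CG" * 50)
        sites_a = [
            CpGSite("c", 2 * i, n_modified=i % 7, n_canonical=7 - i % 7,
                    forward_coverage=7, reverse_coverage=0)
            for i in range(50)
        ]
        # b sees only even-indexed sites, with identical proportions
        sites_b = [s for i, s in enumerate(sites_a) if i % 2 == 0]
        result = shared_site_correlation(sites_a, sites_b, [ref], bin_size=20)
        assert result.r == pytest.approx(1.0)


class TestGCBias:
    def _genome_with_gc_gradient(self):
        rng = np.random.default_rng(0)
        parts = []
        for gc in (20, 30, 40, 50, 60):
            n_gc = gc * 10
            bases = ["G"] * (n_gc // 2) + ["C"] * (n_gc - n_gc // 2)
            bases += ["A"] * ((1000 - n_gc) // 2)
            bases += ["T"] * (1000 - n_gc - (1000 - n_gc) // 2)
            rng.shuffle(bases)
            parts.append("".join(bases))
        return GenomeSequence("c", "".join(parts))

    def test_flat_coverage_is_unity_everywhere(self):
        ref = self._genome_with_gc_gradient()
        depth = [("c", i * 1000, (i + 1) * 1000, 30.0 * 1000) for i in range(5)]
        profile = gc_bias_profile([ref], depth)
        for gc, norm in profile.normalized.items():
            assert norm == pytest.approx(1.0, abs=1e-12)

    def test_injected_step_ratio_recovered(self):
        ref = self._genome_with_gc_gradient()
        depth = []
        for i, gc in enumerate((20, 30, 40, 50, 60)):
            cov = 2.0 if gc < 35 else 0.5
            depth.append(("c", i * 1000, (i + 1) * 1000, cov * 1000))
        profile = gc_bias_profile([ref], depth)
        low = profile.normalized[20]
        high = profile.normalized[60]
        assert low / high == pytest.approx(4.0, rel=1e-9)
        norms = [profile.normalized[gc] for gc in (20, 30, 40, 50, 60)]
        assert all(b <= a for a, b in zip(norms, norms[1:]))

    def test_all_n_bin_excluded(self):
        ref = GenomeSequence("c", "N" * 1000 + "ACGT" * 250)
        depth = [("c", 0, 1000, 10.0), ("c", 1000, 2000, 10.0)]
        profile = gc_bias_profile([ref], depth)
        assert list(profile.mean_coverage) == [50]

    def test_bin_size_mismatch_rejected(self):
        ref = GenomeSequence("c", "ACGT" * 500)
        with pytest.raises(ValueError, match="bin size"):
            gc_bias_profile([ref], [("c", 0, 900, 5.0)])


def make_chain(blocks, target_strand="+", score=100, s_size=1000, t_size=1000,
               s_start=0, t_start=0, source="src", target="tgt"):
    s_span = sum(b.size + b.dt for b in blocks)
    t_span = sum(b.size + b.dq for b in blocks)
    return ChainAlignment(
        score=score, source_name=source, source_size=s_size, source_strand="+",
        source_start=s_start, source_end=s_start + s_span, target_name=target,
        target_size=t_size, target_strand=target_strand, target_start=t_start,
        target_end=t_start + t_span, blocks=tuple(blocks),
    )


class TestLiftover:
    def _records(self, positions, contig="src"):
        return [BedMethylRecord(contig, p, "+", 5, 50.0) for p in positions]

    def test_identity_chain_maps_to_self(self):
        chain = make_chain([ChainBlock(1000, 0, 0)])
        records = self._records([0, 17, 999])
        mapped, unmapped = liftover_sites(records, [chain])
        assert unmapped == []
        assert [r.start for r in mapped] == [0, 17, 999]
        assert all(r.contig == "tgt" for r in mapped)

    def test_position_in_source_gap_unmapped(self):
        chain = make_chain([ChainBlock(10, 5, 0), ChainBlock(10, 0, 0)])
        mapped, unmapped = liftover_sites(self._records([12]), [chain])
        assert mapped == [] and len(unmapped) == 1

    def test_offset_block(self):
        chain = make_chain([ChainBlock(100, 0, 0)], t_start=15)
        (rec,), _ = liftover_sites(self._records([40]), [chain])
        assert rec.start == 55

    def test_conservation_of_record_count(self, rng):
        chain = make_chain(
            [ChainBlock(50, 10, 0), ChainBlock(30, 0, 25), ChainBlock(40, 0, 0)]
        )
        records = self._records(sorted(rng.integers(0, 200, size=80).tolist()))
        mapped, unmapped = liftover_sites(records, [chain])
        assert len(mapped) + len(unmapped) == len(records)

    def test_inverse_chain_round_trip_is_identity(self):
        chain = make_chain(
            [ChainBlock(50, 10, 0), ChainBlock(30, 0, 25), ChainBlock(40, 0, 0)]
        )
        records = self._records(range(0, 130, 7))
        mapped, _ = liftover_sites(records, [chain])
        back, lost = liftover_sites(mapped, [invert_chain(chain)])
        assert lost == []
        mapped_sources = {r.start for r in liftover_sites(records, [chain])[0]}
        assert {r.start for r in back} <= {r.start for r in records}
        assert len(back) == len(mapped)

    def test_target_strand_flip(self):
        chain = make_chain([ChainBlock(100, 0, 0)], target_strand="-", t_size=500)
        (rec,), _ = liftover_sites(self._records([10]), [chain])
        assert rec.start == 500 - 1 - 10
        assert rec.strand == "-"

    def test_highest_score_chain_wins(self):
        low = make_chain([ChainBlock(100, 0, 0)], score=10, t_start=0)
        high = make_chain([ChainBlock(100, 0, 0)], score=99, t_start=200)
        (rec,), _ = liftover_sites(self._records([5]), [low, high])
        assert rec.start == 205

    def test_block_walk_oracle_agreement(self, rng):
        chain = make_chain(
            [
                ChainBlock(37, 4, 0),
                ChainBlock(21, 0, 13),
                ChainBlock(55, 9, 2),
                ChainBlock(30, 0, 0),
            ]
        )
        oracle = walk_chain_positions(chain)
        positions = rng.integers(0, 170, size=300).tolist()
        mapped, unmapped = liftover_sites(self._records(sorted(set(positions))), [chain])
        for rec in unmapped:
            assert rec.start not in oracle
        got = sorted(r.start for r in mapped)
        src_mapped = sorted(
            p for p in set(positions) if p in oracle
        )
        assert got == sorted(oracle[p] for p in src_mapped)
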