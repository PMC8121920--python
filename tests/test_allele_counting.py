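import pandas as pd
import pytest

from allelix.allele_counting import (FilterReason, apply_site_filters,
                                     count_alleles, filter_read,
                                     restrict_to_hotspots)
from allelix.io_formats import GenomicInterval, Indel
from allelix.synthetic_data import _mk_read, simulate_reads_at_snv

ALL_SCENARIOS = ("clean", "low_baseq", "five_prime_offsets", "five_prime_minus",
                 "duplicates", "mismatches", "template_len", "mapq",
                 "genome_discordant", "allele_other", "pair")


class TestFilterRead:
    def test_base_quality_boundary(self, snv):
        r21 = _mk_read(snv, qual=21, mate_id="f", read_id="a")
        r20 = _mk_read(snv, qual=20, mate_id="f", read_id="b")
        assert filter_read(r21, snv).passed
        assert filter_read(r20, snv).reason is FilterReason.LOW_BASEQ

    def test_five_prime_exclusion(self, snv):
        r = _mk_read(snv, offset=2, mate_id="f", read_id="a")
        assert filter_read(r, snv).reason is FilterReason.FIVE_PRIME
        r3 = _mk_read(snv, offset=3, mate_id="f", read_id="b")
        assert filter_read(r3, snv).passed

    def test_five_prime_minus_strand_counts_from_right(self, snv):
        # minus-strand read: the 5' end is the rightmost aligned base
        r = _mk_read(snv, offset=2, strand="-", mate_id="f", read_id="a")
        assert filter_read(r, snv).reason is FilterReason.FIVE_PRIME
        assert r.end - 1 - snv.pos == 2

    def test_mismatch_boundary(self, snv):
        ok = _mk_read(snv, extra_mismatches=2, mate_id="f", read_id="a")
        bad = _mk_read(snv, extra_mismatches=3, mate_id="f", read_id="b")
        assert filter_read(ok, snv).passed
        assert filter_read(bad, snv).reason is FilterReason.MISMATCHES

    def test_template_and_mapq_boundaries(self, snv):
        assert filter_read(_mk_read(snv, tlen=499, mate_id="f", read_id="a"), snv).passed
        assert filter_read(_mk_read(snv, tlen=500, mate_id="f", read_id="b"),
                           snv).reason is FilterReason.TEMPLATE_LEN
        assert filter_read(_mk_read(snv, mapq=20, mate_id="f", read_id="c"), snv).passed
        assert filter_read(_mk_read(snv, mapq=19, mate_id="f", read_id="d"),
                           snv).reason is FilterReason.MAPQ

    def test_decision_order_mapq_before_baseq(self, snv):
        r = _mk_read(snv, mapq=0, qual=0, mate_id="f", read_id="a")
        assert filter_read(r, snv).reason is FilterReason.MAPQ

    def test_non_overlapping_read_is_precondition_error(self, snv):
        far = _mk_read(snv, mate_id="f", read_id="a")
        object.__setattr__(far, "start", snv.pos + 100)
        with pytest.raises(ValueError, match="overlap"):
            filter_read(far, snv)


class TestCountAlleles:
    def test_simple_counting(self, snv):
        reads = [
            _mk_read(snv, offset=4 + i, base=snv.ref_allele,
                     mate_id=f"f{i}", read_id=f"r{i}") for i in range(4)
        ] + [
            _mk_read(snv, offset=10 + i, base=snv.alt_allele,
                     mate_id=f"g{i}", read_id=f"s{i}") for i in range(2)
        ]
        ref, alt, n_over, n_pass, _ = count_alleles(reads, snv)
        assert (ref, alt) == (4, 2)
        assert n_over == 6 and n_pass == 6

    def test_pair_counted_once(self, snv):
        reads = simulate_reads_at_snv(snv, 2, "pair")
        ref, alt, _, n_pass, _ = count_alleles(reads, snv)
        assert (ref, alt, n_pass) == (1, 0, 1)

    def test_duplicates_counted_once(self, snv):
        reads = simulate_reads_at_snv(snv, 3, "duplicates")
        ref, alt, _, _, _ = count_alleles(reads, snv)
        assert (ref, alt) == (1, 0)

    def test_disagreeing_mates_discard_fragment(self, snv):
        reads = [
            _mk_read(snv, offset=5, base=snv.ref_allele, mate_id="f", read_id="a"),
            _mk_read(snv, offset=8, strand="-", base=snv.alt_allele,
                     mate_id="f", read_id="b"),
        ]
        ref, alt, _, n_pass, _ = count_alleles(reads, snv)
        assert (ref, alt, n_pass) == (0, 0, 0)

    def test_order_invariance(self, snv):
        from dataclasses import replace

        reads = []
        for scen in ("clean", "duplicates", "pair"):
            reads += [
                replace(r, mate_id=f"{scen}:{r.mate_id}",
                        read_id=f"{scen}:{r.read_id}")
                for r in simulate_reads_at_snv(snv, 6, scen)
            ]
        fwd = count_alleles(reads, snv)[:4]
        rev = count_alleles(reads[::-1], snv)[:4]
        assert fwd == rev

    def test_counts_bounded_by_fragments(self, snv):
        for scen in ALL_SCENARIOS:
            reads = simulate_reads_at_snv(snv, 8, scen)
            ref, alt, _, _, _ = count_alleles(reads, snv)
            assert ref + alt <= len({r.mate_id for r in reads})

    @pytest.mark.parametrize("scenario", ALL_SCENARIOS)
    def test_decisions_match_generator_labels(self, snv, scenario):
        """Exhaustive confusion matrix: pipeline decision == planted truth."""
        reads = simulate_reads_at_snv(snv, 8, scenario)
        _, _, _, _, decisions = count_alleles(reads, snv)
        for r in reads:
            assert decisions[r.read_id].reason.value == r.truth, (
                f"{scenario}: read {r.read_id} expected {r.truth}, "
                f"got {decisions[r.read_id].reason.value}"
            )


def _counts_frame(rows):
    return pd.DataFrame(rows, columns=[
        "snv_id", "chrom", "pos", "n_overlapping", "n_passing"])


class TestSiteFilters:
    def _mappability(self, snv_ids, value=1.0):
        return pd.DataFrame({"snv_id": snv_ids,
                             "mappable_fraction": [value] * len(snv_ids)})

    def test_indel_distance_boundary(self):
        df = _counts_frame([("a", "chr1", 172, 10, 10),
                            ("b", "chr1", 173, 10, 10)])
        indels = [Indel("chr1", 100, 1)]
        kept, log = apply_site_filters(df, indels, self._mappability(["a", "b"]))
        # 72 bp away -> removed; 73 bp -> retained
        assert list(kept["snv_id"]) == ["b"]
        assert list(log["reason"]) == ["NEAR_INDEL"]

    def test_pass_fraction_boundary(self):
        df = _counts_frame([("a", "chr1", 10, 10, 6),
                            ("b", "chr1", 20, 10, 7)])
        kept, log = apply_site_filters(df, [], self._mappability(["a", "b"]))
        assert list(kept["snv_id"]) == ["b"]

    def test_mappability_boundary(self):
        df = _counts_frame([("a", "chr1", 10, 10, 10),
                            ("b", "chr1", 20, 10, 10),
                            ("c", "chr1", 30, 10, 10)])
        mp = pd.DataFrame({"snv_id": ["a", "b", "c"],
                           "mappable_fraction": [0.95, 0.951, 0.96]})
        kept, _ = apply_site_filters(df, [], mp)
        assert list(kept["snv_id"]) == ["b", "c"]

    def test_missing_mappability_fails_closed(self):
        df = _counts_frame([("a", "chr1", 10, 10, 10)])
        kept, log = apply_site_filters(df, [], self._mappability([]))
        assert kept.empty and list(log["reason"]) == ["LOW_MAPPABILITY"]

    def test_idempotent(self):
        df = _counts_frame([("a", "chr1", 172, 10, 10),
                            ("b", "chr1", 400, 10, 7),
                            ("c", "chr1", 500, 10, 6)])
        mp = self._mappability(["a", "b", "c"])
        indels = [Indel("chr1", 100, 1)]
        once, _ = apply_site_filters(df, indels, mp)
        twice, log2 = apply_site_filters(once, indels, mp)
        pd.testing.assert_frame_equal(once, twice)
        assert log2.empty


class TestHotspotRestriction:
    def test_half_open_overlap(self):
        snvs = pd.DataFrame({"snv_id": ["a", "b"], "chrom": ["chr1", "chr1"],
                             "pos": [100, 200]})
        hs = [GenomicInterval("chr1", 100, 200)]
        testable, background = restrict_to_hotspots(snvs, hs)
        assert list(testable["snv_id"]) == ["a"]   # pos == start is inside
        assert list(background["snv_id"]) == ["b"]  # pos == end is outside

    def test_no_hotspots_all_background(self):
        snvs = pd.DataFrame({"snv_id": ["a"], "chrom": ["chr1"], "pos": [5]})
        testable, background = restrict_to_hotspots(snvs, [])
        assert testable.empty and len(background) == 1

    def test_partition_is_exhaustive(self, small_cohort):
        t, b = restrict_to_hotspots(small_cohort.snvs, small_cohort.dhs_intervals())
        assert len(t) + len(b) == len(small_cohort.snvs)
        assert set(t["snv_id"]).isdisjoint(b["snv_id"])
        # generator marks in-DHS SNVs; the partition must agree with it
        assert set(t["snv_id"]) == set(
            small_cohort.snvs.loc[small_cohort.snvs["dhs_id"] >= 0, "snv_id"])


class TestOptionalSurfaces:
    def test_sam_roundtrip_preserves_records_and_decisions(self, snv):
        from allelix.synthetic_data import (reads_from_sam_text,
                                            reads_to_sam_text,
                                            simulate_reads_at_snv)

        reads = simulate_reads_at_snv(snv, 6, "five_prime_minus")
        back = reads_from_sam_text(reads_to_sam_text(reads))
        assert back == reads
        a = count_alleles(reads, snv)[:4]
        b = count_alleles(back, snv)[:4]
        assert a == b

    def test_excluded_chromosome_goes_to_background(self):
        snvs = pd.DataFrame({"snv_id": ["a", "b"], "chrom": ["chr1", "chrX"],
                             "pos": [150, 150]})
        hs = [GenomicInterval("chr1", 100, 200),
              GenomicInterval("chrX", 100, 200)]
        testable, background = restrict_to_hotspots(snvs, hs,
                                                    exclude_chroms=("chrX",))
        assert list(testable["snv_id"]) == ["a"]
        assert list(background["snv_id"]) == ["b"]
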