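"""Read- and site-level filtering of allele counts at heterozygous SNVs.

Implements the counting rules of the upstream accessibility pipeline:
reads must map concordantly to both parental genomes with adequate
mapping quality and template length; the 3 bp at the 5' end (the DNase
cleavage end, in read orientation) are excluded; the variant base needs
quality >20; at most 2 mismatches beyond the known variant are allowed;
read pairs contribute once; duplicates sharing a 5' position contribute
once. Site-level filters then remove SNVs near indels, with poor
pass-fractions, or with poor simulated mappability.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .io_formats import SNV, GenomicInterval, Indel
from .synthetic_data import SyntheticReadRecord

__all__ = [
    "ReadFilterParams",
    "SiteFilterParams",
    "FilterReason",
    "FilterDecision",
    "filter_read",
    "count_alleles",
    "apply_site_filters",
    "restrict_to_hotspots",
]


@dataclass(frozen=True)
class ReadFilterParams:
    min_base_quality: int = 20          # strict: quality must exceed this
    five_prime_exclusion_bp: int = 3
    max_extra_mismatches: int = 2
    max_template_length_bp: int = 500   # strict: template must be below this
    min_mapq: int = 20                  # inclusive
    require_dual_genome_concordance: bool = True


@dataclass(frozen=True)
class SiteFilterParams:
    indel_exclusion_bp: int = 72        # strict: distance must exceed this
    min_pass_fraction: float = 0.60     # strict (exclusive)
    min_mappable_fraction: float = 0.95  # strict (exclusive)


class FilterReason(str, Enum):
    PASS = "PASS"
    LOW_BASEQ = "LOW_BASEQ"
    FIVE_PRIME = "FIVE_PRIME"
    MISMATCHES = "MISMATCHES"
    TEMPLATE_LEN = "TEMPLATE_LEN"
    MAPQ = "MAPQ"
    GENOME_DISCORDANT = "GENOME_DISCORDANT"
    DUPLICATE = "DUPLICATE"
    PAIR_ALREADY_COUNTED = "PAIR_ALREADY_COUNTED"
    ALLELE_OTHER = "ALLELE_OTHER"


@dataclass(frozen=True)
class FilterDecision:
    passed: bool
    reason: FilterReason
    allele: str | None = None  # "ref"/"alt" when the base matched an allele


def filter_read(read: SyntheticReadRecord, snv: SNV,
                params: ReadFilterParams = ReadFilterParams(),
                duplicate: bool = False) -> FilterDecision:
    """Per-read decision at one SNV, in fixed order.

    Order: mapq -> dual-genome -> template length -> duplicate ->
    5' exclusion -> base quality -> mismatches -> allele identity.
    Duplicate status is group-level information and is supplied by the
    caller (count_alleles resolves it among reads sharing a 5' position).
    """
    if not (read.start <= snv.pos < read.end) or read.chrom != snv.chrom:
        raise ValueError(f"read {read.read_id} does not overlap SNV {snv.snv_id}")
    if read.mapq < params.min_mapq:
        return FilterDecision(False, FilterReason.MAPQ)
    if params.require_dual_genome_concordance and not read.maps_both:
        return FilterDecision(False, FilterReason.GENOME_DISCORDANT)
    if read.tlen >= params.max_template_length_bp:
        return FilterDecision(False, FilterReason.TEMPLATE_LEN)
    if duplicate:
        return FilterDecision(False, FilterReason.DUPLICATE)
    if read.five_prime_offset(snv.pos) < params.five_prime_exclusion_bp:
        return FilterDecision(False, FilterReason.FIVE_PRIME)
    if read.qual_at(snv.pos) <= params.min_base_quality:
        return FilterDecision(False, FilterReason.LOW_BASEQ)
    if read.extra_mismatches > params.max_extra_mismatches:
        return FilterDecision(False, FilterReason.MISMATCHES)
    base = read.base_at(snv.pos)
    if base == snv.ref_allele:
        return FilterDecision(True, FilterReason.PASS, allele="ref")
    if base == snv.alt_allele:
        return FilterDecision(True, FilterReason.PASS, allele="alt")
    return FilterDecision(False, FilterReason.ALLELE_OTHER)


def _five_prime_pos(read: SyntheticReadRecord) -> int:
    """Reference coordinate of the read's 5' end (cleavage end)."""
    return read.end - 1 if read.strand == "-" else read.start


def count_alleles(reads: list[SyntheticReadRecord], snv: SNV,
                  params: ReadFilterParams = ReadFilterParams()
                  ) -> tuple[int, int, int, int, dict]:
    """Count passing fragments per allele at one SNV.

    Returns (ref_count, nonref_count, n_overlapping, n_passing, decisions)
    where `decisions` maps read_id -> FilterDecision. Each fragment (mate
    pair) contributes at most once; mates disagreeing on the allele
    discard the fragment. Among passing fragments whose counted read
    shares a 5' position, exactly one is kept (highest variant base
    quality; ties broken by (chrom, start, mate_id) sort) — independent
    of any duplicate flag on the records.
    """
    # deterministic processing order regardless of input order
    reads = sorted(reads, key=lambda r: (r.chrom, r.start, r.mate_id, r.read_id))
    n_overlapping = len(reads)
    decisions: dict[str, FilterDecision] = {}

    # per-read filters first (without duplicate resolution)
    prelim: dict[str, FilterDecision] = {}
    for r in reads:
        prelim[r.read_id] = filter_read(r, snv, params)

    # fragment resolution: one counted read per mate pair
    by_frag: dict[str, list[SyntheticReadRecord]] = {}
    for r in reads:
        by_frag.setdefault(r.mate_id, []).append(r)

    candidates = []  # (read, allele) — one per fragment, pre-duplicate
    for frag_id, frag_reads in sorted(by_frag.items()):
        passing = [r for r in frag_reads if prelim[r.read_id].passed]
        for r in frag_reads:
            if not prelim[r.read_id].passed:
                decisions[r.read_id] = prelim[r.read_id]
        if not passing:
            continue
        alleles = {prelim[r.read_id].allele for r in passing}
        if len(alleles) > 1:
            # mates disagree on the allele: discard the whole fragment
            for r in passing:
                decisions[r.read_id] = FilterDecision(
                    False, FilterReason.ALLELE_OTHER, allele=None)
            continue
        # count once; the mate with the best variant base quality represents
        # the fragment, the other is recorded as already counted
        rep = max(passing, key=lambda r: (r.qual_at(snv.pos), -r.start))
        for r in passing:
            if r is not rep:
                decisions[r.read_id] = FilterDecision(
                    False, FilterReason.PAIR_ALREADY_COUNTED)
        candidates.append((rep, prelim[rep.read_id].allele))

    # duplicate resolution among candidate fragments sharing a 5' position
    by_5p: dict[int, list[tuple[SyntheticReadRecord, str]]] = {}
    for r, allele in candidates:
        by_5p.setdefault(_five_prime_pos(r), []).append((r, allele))
    ref = alt = 0
    for pos5 in sorted(by_5p):
        group = sorted(by_5p[pos5],
                       key=lambda ra: (-ra[0].qual_at(snv.pos), ra[0].chrom,
                                       ra[0].start, ra[0].mate_id))
        keep, allele = group[0]
        decisions[keep.read_id] = FilterDecision(True, FilterReason.PASS, allele=allele)
        for r, _ in group[1:]:
            decisions[r.read_id] = FilterDecision(False, FilterReason.DUPLICATE)
        if allele == "ref":
            ref += 1
        else:
            alt += 1
    n_passing = ref + alt
    return ref, alt, n_overlapping, n_passing, decisions


def apply_site_filters(per_snv_counts: pd.DataFrame, indels: list[Indel],
                       mappability: pd.DataFrame,
                       params: SiteFilterParams = SiteFilterParams()
                       ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop SNVs near indels, with poor pass-fraction or poor mappability.

    `per_snv_counts` needs columns snv_id, chrom, pos, n_overlapping,
    n_passing (count columns are carried through untouched). Missing
    mappability entries fail closed. Returns (retained, rejection_log);
    the log has one row per removed SNV with the first failing reason.
    Idempotent: retained rows all pass on re-application.
    """
    df = per_snv_counts.copy()
    mp = mappability.set_index("snv_id")["mappable_fraction"]

    indel_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for ind in indels:
        indel_by_chrom.setdefault(ind.chrom, []).append(ind.span)

    def near_indel(chrom: str, pos: int) -> bool:
        for s, e in indel_by_chrom.get(chrom, ()):
            # distance from pos to the indel's reference footprint
            d = max(s - pos, pos - (e - 1), 0)
            if d <= params.indel_exclusion_bp:
                return True
        return False

    reasons = []
    keep = np.ones(len(df), dtype=bool)
    for i, row in enumerate(df.itertuples(index=False)):
        if near_indel(row.chrom, row.pos):
            keep[i] = False
            reasons.append((row.snv_id, "NEAR_INDEL"))
            continue
        if row.n_overlapping > 0 and row.n_passing / row.n_overlapping <= params.min_pass_fraction:
            keep[i] = False
            reasons.append((row.snv_id, "LOW_PASS_FRACTION"))
            continue
        frac = mp.get(row.snv_id, 0.0)  # fail closed on missing entries
        if frac <= params.min_mappable_fraction:
            keep[i] = False
            reasons.append((row.snv_id, "LOW_MAPPABILITY"))
    retained = df[keep].reset_index(drop=True)
    log = pd.DataFrame(reasons, columns=["snv_id", "reason"])
    return retained, log


def restrict_to_hotspots(snvs: pd.DataFrame, hotspots: list[GenomicInterval],
                         exclude_chroms: tuple[str, ...] = ()
                         ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition mappable SNVs into testable (in a hotspot) and background.

    Overlap uses the half-open convention: pos in [start, end). The
    partition is exhaustive — every input SNV lands in exactly one set.
    `exclude_chroms` (e.g. a sex chromosome) routes whole chromosomes to
    the background set regardless of hotspot overlap.
    """
    trees: dict[str, IntervalTree] = {}
    for iv in hotspots:
        if iv.chrom in exclude_chroms:
            continue
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end)
    in_dhs = np.array([
        bool(r.chrom not in exclude_chroms and trees.get(r.chrom)
             and trees[r.chrom].overlaps_point(r.pos))
        for r in snvs.itertuples(index=False)
    ], dtype=bool) if len(snvs) else np.array([], dtype=bool)
    testable = snvs[in_dhs].reset_index(drop=True)
    background = snvs[~in_dhs].reset_index(drop=True)
    return testable, background
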