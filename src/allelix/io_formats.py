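"""Readers and writers for the genomic text formats the pipeline touches.

All in-memory coordinates are 0-based half-open. VCF input (1-based) is
converted at the boundary; BED input is already 0-based half-open and is
kept verbatim. Chromosome names are opaque strings — no "chr" aliasing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

_VALID_BASES = frozenset("ACGT")
_VALID_STRANDS = frozenset("+-.")


class ParseError(ValueError):
    """A malformed line that cannot be interpreted; carries the line number."""


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open interval, optionally stranded/named/scored."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str | None = None
    score: float | None = None

    def __post_init__(self):
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start >= self.end:
            raise ValueError(f"empty interval: start={self.start} >= end={self.end}")
        if self.strand not in _VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos < self.end


@dataclass(frozen=True)
class SNV:
    """A heterozygous point variant — the unit of allelic testing."""

    chrom: str
    pos: int  # 0-based
    ref_allele: str
    alt_allele: str
    strain_id: str = ""
    snv_id: str = ""

    def __post_init__(self):
        if self.ref_allele not in _VALID_BASES or self.alt_allele not in _VALID_BASES:
            raise ValueError(
                f"alleles must be single ACGT bases, got "
                f"{self.ref_allele!r}/{self.alt_allele!r}"
            )
        if self.ref_allele == self.alt_allele:
            raise ValueError("ref and alt alleles must differ")
        if not self.snv_id:
            object.__setattr__(self, "snv_id", f"{self.chrom}:{self.pos}")


@dataclass(frozen=True)
class Indel:
    """An insertion (length > 0) or deletion (length < 0), 0-based anchor."""

    chrom: str
    pos: int
    length: int

    def __post_init__(self):
        if self.length == 0:
            raise ValueError("indel length must be non-zero")

    @property
    def span(self) -> tuple[int, int]:
        """Affected reference footprint as a half-open interval.

        An insertion occupies a single anchor base; a deletion covers the
        deleted reference bases.
        """
        if self.length > 0:
            return (self.pos, self.pos + 1)
        return (self.pos, self.pos - self.length)


def read_variants(path) -> tuple[list[SNV], list[Indel]]:
    """Parse a minimal 5-column VCF into SNVs and indels.

    POS is converted from 1-based VCF to 0-based internal coordinates.
    Multi-allelic records are split into one record per ALT. Records whose
    REF and ALT are both single bases become SNVs; anything else becomes an
    Indel with signed length ``len(ALT) - len(REF)``. SNV records with a
    non-ACGT allele are dropped with a warning.
    """
    snvs: list[SNV] = []
    indels: list[Indel] = []
    n_rejected = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 5:
                raise ParseError(f"line {lineno}: expected >=5 columns, got {len(fields)}")
            chrom, pos_s, vid, ref, alts = fields[:5]
            try:
                pos = int(pos_s) - 1
            except ValueError as exc:
                raise ParseError(f"line {lineno}: non-integer POS {pos_s!r}") from exc
            if pos < 0:
                raise ParseError(f"line {lineno}: POS must be >= 1")
            for alt in alts.split(","):
                if len(ref) == 1 and len(alt) == 1:
                    try:
                        snv_id = vid if vid not in (".", "") else ""
                        snvs.append(
                            SNV(chrom=chrom, pos=pos, ref_allele=ref.upper(),
                                alt_allele=alt.upper(), snv_id=snv_id)
                        )
                    except ValueError:
                        n_rejected += 1
                else:
                    # VCF indel anchors on the shared leading base; the event
                    # itself starts one base to the right for deletions.
                    indels.append(Indel(chrom=chrom, pos=pos, length=len(alt) - len(ref)))
    if n_rejected:
        warnings.warn(f"rejected {n_rejected} SNV record(s) with non-ACGT alleles")
    return snvs, indels


def read_bed(path) -> list[GenomicInterval]:
    """Parse BED3+ (0-based half-open); name/score/strand carried if present.

    Zero-length or inverted intervals are rejected record-by-record with a
    summary warning rather than aborting the parse.
    """
    intervals: list[GenomicInterval] = []
    n_rejected = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 3:
                raise ParseError(f"line {lineno}: expected >=3 columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"line {lineno}: non-integer coordinates") from exc
            name = fields[3] if len(fields) > 3 else None
            score = None
            if len(fields) > 4 and fields[4] not in (".", ""):
                score = float(fields[4])
            strand = fields[5] if len(fields) > 5 else "."
            try:
                intervals.append(
                    GenomicInterval(chrom=chrom, start=start, end=end,
                                    strand=strand, name=name, score=score)
                )
            except ValueError:
                n_rejected += 1
    if n_rejected:
        warnings.warn(f"rejected {n_rejected} empty/inverted BED record(s)")
    return intervals


@dataclass
class AlleleCountMatrix:
    """Per-(SNV, condition) reference/non-reference read counts.

    The pipeline's central tensor, stored long-form. Duplicate keys are
    summed on insertion, matching the pooling of replicate samples.
    """

    counts: dict[tuple[str, str], tuple[int, int]] = field(default_factory=dict)

    def add(self, snv_id: str, condition_id: str, ref_count: int, nonref_count: int):
        if ref_count < 0 or nonref_count < 0:
            raise ValueError(
                f"negative count for ({snv_id}, {condition_id}): "
                f"({ref_count}, {nonref_count})"
            )
        key = (snv_id, condition_id)
        r0, n0 = self.counts.get(key, (0, 0))
        self.counts[key] = (r0 + ref_count, n0 + nonref_count)

    def get(self, snv_id: str, condition_id: str) -> tuple[int, int]:
        return self.counts.get((snv_id, condition_id), (0, 0))

    def __len__(self) -> int:
        return len(self.counts)

    def to_frame(self) -> pd.DataFrame:
        if not self.counts:
            return pd.DataFrame(
                columns=["snv_id", "condition_id", "ref_count", "nonref_count"]
            )
        rows = [
            (s, c, r, n) for (s, c), (r, n) in self.counts.items()
        ]
        df = pd.DataFrame(rows, columns=["snv_id", "condition_id", "ref_count", "nonref_count"])
        return df.sort_values(["snv_id", "condition_id"], ignore_index=True)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "AlleleCountMatrix":
        m = cls()
        for row in df.itertuples(index=False):
            m.add(str(row.snv_id), str(row.condition_id),
                  int(row.ref_count), int(row.nonref_count))
        return m


def read_count_table(path) -> AlleleCountMatrix:
    """Read a TSV of (snv_id, condition_id, ref_count, nonref_count)."""
    df = pd.read_csv(path, sep="\t", dtype={"snv_id": str, "condition_id": str})
    if df.empty:
        return AlleleCountMatrix()
    required = {"snv_id", "condition_id", "ref_count", "nonref_count"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"count table missing columns: {sorted(missing)}")
    if (df[["ref_count", "nonref_count"]] < 0).any().any():
        raise ValueError("negative counts in count table")
    return AlleleCountMatrix.from_frame(df)


def write_count_table(matrix: AlleleCountMatrix, path):
    matrix.to_frame().to_csv(path, sep="\t", index=False)


_CALL_SORT_COLS = ["chrom", "pos", "group_id"]


def write_results(calls: pd.DataFrame, path_prefix, profiles: pd.DataFrame | None = None):
    """Write result tables with deterministic column order and row sort.

    Floats are serialized with enough digits (%.8g) that reading the file
    back reproduces values to 1e-6. Returns the list of files written.
    """
    prefix = Path(path_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    written = []
    calls = calls.copy()
    sort_cols = [c for c in _CALL_SORT_COLS if c in calls.columns]
    if sort_cols:
        calls = calls.sort_values(sort_cols, ignore_index=True)
    calls_path = prefix.with_name(prefix.name + ".calls.tsv")
    calls.to_csv(calls_path, sep="\t", index=False, float_format="%.8g")
    written.append(calls_path)
    if profiles is not None:
        prof_path = prefix.with_name(prefix.name + ".profiles.tsv")
        profiles.to_csv(prof_path, sep="\t", index=False, float_format="%.8g")
        written.append(prof_path)
    return written


def read_results(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
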