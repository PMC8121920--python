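"""TF-motif sensitivity profiles from allelic-imbalance calls.

Tested SNVs are intersected with motif matches (one best instance per
SNV per motif, by match p-value); per-position tallies of tested and
imbalanced SNVs form a sensitivity profile in motif orientation.
Profiles passing a data-sufficiency QC are summarized as core-vs-flank
and per-cell-type enrichments, and imbalance rates are stratified by
footprint presence and motif-match stringency.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

__all__ = [
    "MotifPositionProfile",
    "best_instance_per_snv",
    "snv_motif_assignments",
    "build_position_profile",
    "motif_qc_filter",
    "core_flank_enrichment",
    "celltype_enrichment",
    "footprint_stratified_rates",
    "overall_motif_overlap",
    "wilson_interval",
]

MIN_SNVS_PER_POSITION = 7  # fewer tested SNVs -> position is missing data
STRINGENT_MATCH_P = 1e-5


def best_instance_per_snv(matches: pd.DataFrame) -> pd.Series:
    """Pick the best match (minimal p-value) among instances of one motif.

    Ties break deterministically: leftmost start, then '+' strand.
    `matches` rows are instances of a single motif overlapping one SNV.
    Returns the winning row as a Series.
    """
    if matches.empty:
        raise ValueError("no overlapping matches")
    m = matches.sort_values(
        ["pvalue", "start", "strand"], ascending=[True, True, True],
        kind="stable",
    )
    return m.iloc[0]


def _motif_position(snv_pos: int, start: int, width: int, strand: str) -> int:
    """SNV offset within the motif, in motif orientation."""
    g = snv_pos - start
    return width - 1 - g if strand == "-" else g


def snv_motif_assignments(snvs: pd.DataFrame, matches: pd.DataFrame
                          ) -> pd.DataFrame:
    """Assign each SNV its best instance per overlapping motif.

    Matches are deduplicated by (motif_id, chrom, start, strand) first —
    the union of reference- and strain-genome scans collapses to a
    non-redundant list. Returns long-form rows (snv_id, motif_id,
    position, strand, score, pvalue, match_id) with `position` in motif
    orientation.
    """
    dedup = matches.drop_duplicates(subset=["motif_id", "chrom", "start", "strand"])
    trees: dict[str, IntervalTree] = {}
    for i, row in enumerate(dedup.itertuples(index=False)):
        trees.setdefault(row.chrom, IntervalTree()).addi(row.start, row.end, i)
    dd = dedup.reset_index(drop=True)
    rows = []
    for snv in snvs.itertuples(index=False):
        tree = trees.get(snv.chrom)
        if tree is None:
            continue
        hits = [iv.data for iv in tree[snv.pos]]
        if not hits:
            continue
        sub = dd.iloc[hits]
        for motif_id, msub in sub.groupby("motif_id"):
            best = best_instance_per_snv(msub)
            width = int(best["end"] - best["start"])
            pos = _motif_position(snv.pos, int(best["start"]), width, best["strand"])
            rows.append((snv.snv_id, motif_id, pos, best["strand"],
                         best["score"], best["pvalue"],
                         best.get("match_id", ""), int(best["start"]),
                         int(best["end"]),
                         float(best.get("logodds_diff", 0.0))))
    return pd.DataFrame(rows, columns=[
        "snv_id", "motif_id", "position", "strand", "score", "pvalue",
        "match_id", "match_start", "match_end", "logodds_diff",
    ])


@dataclass
class MotifPositionProfile:
    motif_id: str
    width: int
    n_tested: np.ndarray      # per position
    n_imbalanced: np.ndarray
    missing: np.ndarray       # bool per position: n_tested < 7

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "motif_id": self.motif_id,
            "position": np.arange(self.width),
            "n_tested": self.n_tested,
            "n_imbalanced": self.n_imbalanced,
            "missing": self.missing,
        })


def build_position_profile(assignments: pd.DataFrame, calls: pd.DataFrame,
                           motif_id: str, width: int) -> MotifPositionProfile:
    """Per-position tested/imbalanced tallies for one motif.

    `assignments` comes from snv_motif_assignments; `calls` carries
    snv_id + imbalanced for the pooling analysis under study. Positions
    with fewer than 7 tested SNVs are flagged missing.
    """
    sub = assignments[assignments["motif_id"] == motif_id]
    tested_ids = set(calls["snv_id"])
    imb_ids = set(calls.loc[calls["imbalanced"], "snv_id"])
    n_tested = np.zeros(width, dtype=int)
    n_imb = np.zeros(width, dtype=int)
    for row in sub.itertuples(index=False):
        if row.snv_id not in tested_ids:
            continue
        if not 0 <= row.position < width:
            continue
        n_tested[row.position] += 1
        if row.snv_id in imb_ids:
            n_imb[row.position] += 1
    return MotifPositionProfile(
        motif_id=motif_id, width=width, n_tested=n_tested, n_imbalanced=n_imb,
        missing=n_tested < MIN_SNVS_PER_POSITION,
    )


def motif_qc_filter(profile: MotifPositionProfile,
                    min_median_tested: int = 40,
                    min_positions_with_significant: int = 3,
                    min_significant_per_position: int = 7) -> bool:
    """Data-sufficiency gate for reporting a motif's profile.

    Pass iff the median over positions of tested SNVs is >= 40 and at
    least 3 positions carry >= 7 imbalanced SNVs.
    """
    if profile.width == 0:
        return False
    median_tested = float(np.median(profile.n_tested))
    n_sig_pos = int((profile.n_imbalanced >= min_significant_per_position).sum())
    return (median_tested >= min_median_tested
            and n_sig_pos >= min_positions_with_significant)


def _log2_rate_ratio(k1, n1, k2, n2, pseudocount=0.5):
    psi = pseudocount
    return float(np.log2(((k1 + psi) / (n1 + psi)) / ((k2 + psi) / (n2 + psi))))


def core_flank_enrichment(core_tested: int, core_imbalanced: int,
                          flank_tested: int, flank_imbalanced: int,
                          pseudocount: float = 0.5) -> float:
    """log2 imbalance-rate ratio, motif core vs flanking sequence.

    Haldane-Anscombe pseudocount keeps the statistic finite; it is
    antisymmetric under exchanging core and flank tallies.
    """
    return _log2_rate_ratio(core_imbalanced, core_tested,
                            flank_imbalanced, flank_tested, pseudocount)


def flank_tallies(snvs: pd.DataFrame, assignments: pd.DataFrame,
                  calls: pd.DataFrame, motif_id: str,
                  flank_bp: int = 10) -> tuple[int, int]:
    """Tested/imbalanced counts in +-flank_bp around this motif's matches,
    excluding SNVs inside any match of the same motif."""
    sub = assignments[assignments["motif_id"] == motif_id]
    if sub.empty:
        return 0, 0
    tree: dict[str, IntervalTree] = {}
    inside: dict[str, IntervalTree] = {}
    snv_chrom = snvs.set_index("snv_id")["chrom"]
    for row in sub.drop_duplicates("match_id").itertuples(index=False):
        chrom = snv_chrom.get(row.snv_id)
        tree.setdefault(chrom, IntervalTree()).addi(
            row.match_start - flank_bp, row.match_end + flank_bp)
        inside.setdefault(chrom, IntervalTree()).addi(row.match_start, row.match_end)
    tested = imb = 0
    imb_ids = set(calls.loc[calls["imbalanced"], "snv_id"])
    tested_ids = set(calls["snv_id"])
    for snv in snvs.itertuples(index=False):
        if snv.snv_id not in tested_ids:
            continue
        t = tree.get(snv.chrom)
        if t is None or not t.overlaps_point(snv.pos):
            continue
        ins = inside.get(snv.chrom)
        if ins is not None and ins.overlaps_point(snv.pos):
            continue
        tested += 1
        if snv.snv_id in imb_ids:
            imb += 1
    return tested, imb


def celltype_enrichment(assignments: pd.DataFrame, snvs: pd.DataFrame,
                        calls_by_celltype: dict[str, pd.DataFrame],
                        motif_id: str, core: tuple[int, int],
                        flank_bp: int = 10, gate_log2: float = 1.0
                        ) -> pd.DataFrame:
    """Core-vs-flank enrichment within each cell type's calls.

    The boolean gate (log2 enrichment strictly > `gate_log2`, i.e. more
    than twofold) selects cell types whose imbalance data train this
    motif's TF model. Cell types with no tested SNV in the motif are
    masked (NaN enrichment, gate False).
    """
    sub = assignments[assignments["motif_id"] == motif_id]
    rows = []
    for ct, calls in calls_by_celltype.items():
        tested_ids = set(calls["snv_id"])
        imb_ids = set(calls.loc[calls["imbalanced"], "snv_id"])
        in_core = sub[(sub["position"] >= core[0]) & (sub["position"] < core[1])]
        core_tested = int(in_core["snv_id"].isin(tested_ids).sum())
        core_imb = int(in_core["snv_id"].isin(imb_ids).sum())
        fl_tested, fl_imb = flank_tallies(snvs, assignments, calls, motif_id, flank_bp)
        if core_tested == 0:
            rows.append((motif_id, ct, np.nan, False, 0, 0, fl_tested, fl_imb))
            continue
        enr = core_flank_enrichment(core_tested, core_imb, fl_tested, fl_imb)
        rows.append((motif_id, ct, enr, enr > gate_log2,
                     core_tested, core_imb, fl_tested, fl_imb))
    return pd.DataFrame(rows, columns=[
        "motif_id", "cell_type", "log2_enrichment", "gate",
        "core_tested", "core_imbalanced", "flank_tested", "flank_imbalanced",
    ])


def wilson_interval(k: int, n: int, z: float = 1.959963984540054
                    ) -> tuple[float, float]:
    """Wilson 95% score interval for a binomial proportion."""
    if n == 0:
        return (np.nan, np.nan)
    phat = k / n
    denom = 1 + z**2 / n
    center = (phat + z**2 / (2 * n)) / denom
    half = z * np.sqrt(phat * (1 - phat) / n + z**2 / (4 * n**2)) / denom
    return (max(0.0, center - half), min(1.0, center + half))


def footprint_stratified_rates(calls: pd.DataFrame, snvs: pd.DataFrame,
                               assignments: pd.DataFrame,
                               footprints: pd.DataFrame,
                               pvalue_bins=(1e-7, 1e-5, 1e-3)) -> pd.DataFrame:
    """Imbalance frequency by footprint presence x motif stringency.

    SNVs with no overlapping motif form the "no_motif" stratum; others
    are binned by the best (smallest) match p-value across motifs.
    Frequencies carry Wilson 95% intervals.
    """
    fp_tree: dict[str, IntervalTree] = {}
    for row in footprints.itertuples(index=False):
        fp_tree.setdefault(row.chrom, IntervalTree()).addi(row.start, row.end)
    best_p = assignments.groupby("snv_id")["pvalue"].min()
    pos_of = snvs.set_index("snv_id")[["chrom", "pos"]]

    edges = list(pvalue_bins)
    labels = [f"p<{edges[0]:g}"]
    labels += [f"{edges[i]:g}<=p<{edges[i+1]:g}" for i in range(len(edges) - 1)]
    labels += [f"p>={edges[-1]:g}"]

    rows = []
    tallies: dict[tuple[bool, str], list[int]] = {}
    for row in calls.itertuples(index=False):
        if row.snv_id not in pos_of.index:
            continue
        chrom, pos = pos_of.loc[row.snv_id]
        t = fp_tree.get(chrom)
        in_fp = bool(t is not None and t.overlaps_point(pos))
        p = best_p.get(row.snv_id, np.nan)
        if np.isnan(p):
            stratum = "no_motif"
        else:
            stratum = labels[int(np.searchsorted(edges, p, side="right"))]
        key = (in_fp, stratum)
        k, n = tallies.get(key, (0, 0))
        tallies[key] = (k + int(bool(row.imbalanced)), n + 1)
    for (in_fp, stratum), (k, n) in sorted(tallies.items()):
        lo, hi = wilson_interval(k, n)
        rows.append((in_fp, stratum, k, n, k / n if n else np.nan, lo, hi))
    return pd.DataFrame(rows, columns=[
        "footprint", "stratum", "n_imbalanced", "n_tested", "rate",
        "ci_lo", "ci_hi",
    ])


def overall_motif_overlap(calls: pd.DataFrame, snvs: pd.DataFrame,
                          matches: pd.DataFrame,
                          max_pvalue: float = STRINGENT_MATCH_P
                          ) -> tuple[float, int, int]:
    """Fraction of imbalanced SNVs overlapping a stringent motif match.

    Returns (fraction, numerator, denominator).
    """
    stringent = matches[matches["pvalue"] < max_pvalue]
    trees: dict[str, IntervalTree] = {}
    for row in stringent.itertuples(index=False):
        trees.setdefault(row.chrom, IntervalTree()).addi(row.start, row.end)
    imb = calls.loc[calls["imbalanced"], "snv_id"]
    pos_of = snvs.set_index("snv_id")[["chrom", "pos"]]
    denom = 0
    num = 0
    for sid in imb:
        if sid not in pos_of.index:
            continue
        chrom, pos = pos_of.loc[sid]
        denom += 1
        t = trees.get(chrom)
        if t is not None and t.overlaps_point(pos):
            num += 1
    return (num / denom if denom else 0.0), num, denom
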