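"""Synthetic cohort generator for allele-specific accessibility analysis.

Generates every input the downstream stages consume — heterozygous SNVs
placed inside and outside DNase hotspots across strains and cell types,
allele counts drawn beta-binomially around condition-specific true
allelic ratios, motif architectures with causal effects concentrated at
core positions, footprints, genomic annotations, and transcript-level
allelic counts coupled to nearby accessibility effects by a
distance-decaying kernel.

Defaults emulate the study design: 4 cell types, F1-hybrid strains (each
SNV heterozygous in exactly one hybrid), heavy-tailed read depths
spanning the 30-read test and 100-read dispersion-fit thresholds, a 5%
causal fraction with effect sizes |theta - 0.5| ~ Uniform(0.15, 0.45).
Everything is deterministic for a given seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .imbalance import sample_betabinom
from .io_formats import SNV, GenomicInterval, Indel

_BASES = np.array(list("ACGT"))

# ground-truth filter labels shared with allele_counting
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
class SimConfig:
    """Knobs of the synthetic cohort; the seed is mandatory.

    Dispersion `rho` applies to every condition unless `rho_by_condition`
    overrides specific (cell_type, strain) pairs.
    """

    seed: int
    n_snvs: int = 50_000
    cell_types: tuple[str, ...] = ("liver", "kidney", "lung", "bcell")
    strains: tuple[str, ...] = ("s129", "scast")
    # read depth: negative binomial truncated to [depth_min, depth_max]
    depth_mean: float = 60.0
    depth_shape: float = 2.0
    depth_min: int = 10
    depth_max: int = 2000
    rho: float = 0.03
    rho_by_condition: dict = field(default_factory=dict)
    fraction_causal: float = 0.05
    effect_lo: float = 0.15
    effect_hi: float = 0.45
    shared_effect_fraction: float = 0.6  # causal in all cell types vs one
    # genome layout
    n_chroms: int = 2
    dhs_snv_fraction: float = 0.7  # SNVs placed inside hotspots
    snvs_per_dhs: float = 2.0
    dhs_width_lo: int = 150
    dhs_width_hi: int = 400
    dhs_gap_mean: float = 2_000.0
    indel_fraction: float = 0.01  # indels per SNV
    # motif architecture
    n_motifs: int = 20
    motif_width_lo: int = 8
    motif_width_hi: int = 16
    fraction_causal_in_motif: float = 0.6
    noise_match_fraction: float = 0.3  # null SNVs also overlapping a motif
    motif_celltype_specific_fraction: float = 0.5
    footprint_fraction: float = 0.5
    # annotations
    n_catalogs: int = 45
    n_genes_per_chrom: int = 500

    def __post_init__(self):
        if not 0 <= self.fraction_causal <= 1:
            raise ValueError(f"fraction_causal must be in [0,1], got {self.fraction_causal}")
        if not 0 <= self.rho < 1:
            raise ValueError(f"rho must be in [0,1), got {self.rho}")
        if self.seed is None:
            raise ValueError("seed is mandatory")

    def condition_rho(self, cell_type: str, strain: str) -> float:
        return self.rho_by_condition.get((cell_type, strain), self.rho)


@dataclass
class Cohort:
    """Everything simulate_cohort produces, as plain DataFrames.

    `snvs`: snv_id, chrom, pos, ref, alt, strain, dhs_id (-1 if outside).
    `true_effects`: causal flag, causal motif/position, and one
    theta_<cell_type> column per cell type (0.5 everywhere for nulls).
    `counts`: long-form (snv_id, condition_id, ref_count, nonref_count)
    where condition_id = "<cell_type>.<strain>" and each SNV is observed
    only in its own hybrid's conditions.
    """

    config: SimConfig
    snvs: pd.DataFrame
    indels: list
    dhs: pd.DataFrame
    motifs: pd.DataFrame
    motif_matches: pd.DataFrame
    footprints: pd.DataFrame
    true_effects: pd.DataFrame
    counts: pd.DataFrame
    annotations: pd.DataFrame
    catalog_membership: np.ndarray
    tss: pd.DataFrame

    @property
    def conditions(self) -> list[str]:
        return [f"{c}.{s}" for c in self.config.cell_types for s in self.config.strains]

    def scheme_frame(self) -> pd.DataFrame:
        """One sample per (cell type, strain); sample_id == condition_id."""
        rows = [
            (f"{c}.{s}", c, s)
            for c in self.config.cell_types for s in self.config.strains
        ]
        return pd.DataFrame(rows, columns=["sample_id", "cell_type", "strain"])

    def dhs_intervals(self) -> list[GenomicInterval]:
        return [
            GenomicInterval(r.chrom, int(r.start), int(r.end), name=str(r.dhs_id))
            for r in self.dhs.itertuples(index=False)
        ]

    def theta_matrix(self) -> pd.DataFrame:
        """True allelic ratio per (snv, condition); NaN where unobserved."""
        cfg = self.config
        out = {}
        strain = self.snvs["strain"].to_numpy()
        for c in cfg.cell_types:
            theta = self.true_effects[f"theta_{c}"].to_numpy()
            for s in cfg.strains:
                col = np.where(strain == s, theta, np.nan)
                out[f"{c}.{s}"] = col
        return pd.DataFrame(out, index=self.snvs["snv_id"])


def _truncated_nbinom_depth(rng, size, mean, shape, lo, hi):
    """Heavy-tailed depths clipped by resampling into [lo, hi]."""
    p = shape / (shape + mean)
    d = rng.negative_binomial(shape, p, size=size)
    bad = (d < lo) | (d > hi)
    # a couple of resampling passes, then clip the stragglers
    for _ in range(4):
        if not bad.any():
            break
        d[bad] = rng.negative_binomial(shape, p, size=int(bad.sum()))
        bad = (d < lo) | (d > hi)
    return np.clip(d, lo, hi)


def simulate_cohort(config: SimConfig) -> Cohort:
    """Generate a full synthetic cohort; deterministic for a given seed."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_snvs
    cell_types = list(cfg.cell_types)
    n_ct = len(cell_types)

    # --- genome layout: DHS hotspots along each chromosome -----------------
    n_dhs = max(1, int(round(n * cfg.dhs_snv_fraction / cfg.snvs_per_dhs)))
    per_chrom = np.full(cfg.n_chroms, n_dhs // cfg.n_chroms)
    per_chrom[: n_dhs % cfg.n_chroms] += 1
    dhs_rows = []
    chrom_len = {}
    dhs_id = 0
    for ci in range(cfg.n_chroms):
        chrom = f"chr{ci + 1}"
        pos = 1000
        for _ in range(int(per_chrom[ci])):
            gap = int(rng.exponential(cfg.dhs_gap_mean)) + 200
            width = int(rng.integers(cfg.dhs_width_lo, cfg.dhs_width_hi + 1))
            start = pos + gap
            dhs_rows.append((dhs_id, chrom, start, start + width))
            pos = start + width
            dhs_id += 1
        chrom_len[chrom] = pos + 10_000
    dhs = pd.DataFrame(dhs_rows, columns=["dhs_id", "chrom", "start", "end"])
    dhs["strength"] = rng.lognormal(mean=0.0, sigma=0.7, size=len(dhs))
    dhs["width"] = dhs["end"] - dhs["start"]

    # --- SNVs: most inside hotspots, the rest in the gaps ------------------
    n_in = int(round(n * cfg.dhs_snv_fraction))
    in_dhs_idx = rng.integers(0, len(dhs), size=n_in)
    in_pos = dhs["start"].to_numpy()[in_dhs_idx] + (
        rng.random(n_in) * dhs["width"].to_numpy()[in_dhs_idx]
    ).astype(np.int64)
    in_chrom = dhs["chrom"].to_numpy()[in_dhs_idx]
    n_out = n - n_in
    out_chrom_i = rng.integers(0, cfg.n_chroms, size=n_out)
    out_chrom = np.array([f"chr{i + 1}" for i in out_chrom_i])
    out_pos = np.array([
        int(rng.integers(0, chrom_len[c])) for c in out_chrom
    ], dtype=np.int64)
    # background SNVs are "not in a hotspot" by construction: nudge any
    # collision out of its DHS
    chrom_arr = np.concatenate([in_chrom, out_chrom])
    pos_arr = np.concatenate([in_pos, out_pos])
    dhs_assign = np.concatenate([in_dhs_idx, np.full(n_out, -1, dtype=np.int64)])
    # DHS gaps are >= 200 bp, so a < 200 bp nudge past the end cannot land
    # inside the next hotspot
    for ci in range(cfg.n_chroms):
        chrom = f"chr{ci + 1}"
        starts = dhs.loc[dhs["chrom"] == chrom, "start"].to_numpy()
        ends = dhs.loc[dhs["chrom"] == chrom, "end"].to_numpy()
        rows = np.flatnonzero((chrom_arr == chrom)
                              & (np.arange(n) >= n_in))
        if not len(rows) or not len(starts):
            continue
        idx = np.searchsorted(starts, pos_arr[rows], side="right") - 1
        inside = (idx >= 0) & (pos_arr[rows] < ends[np.clip(idx, 0, None)])
        hit_rows = rows[inside]
        pos_arr[hit_rows] = ends[idx[inside]] + rng.integers(1, 200, size=len(hit_rows))

    # sort by (chrom, pos) and work in sorted space from here on, so every
    # per-SNV array below is aligned with the table row by row
    order = np.lexsort((pos_arr, chrom_arr))
    chrom_arr = chrom_arr[order]
    pos_arr = pos_arr[order]
    dhs_assign = dhs_assign[order]
    ref_i = rng.integers(0, 4, size=n)
    alt_i = (ref_i + rng.integers(1, 4, size=n)) % 4
    strain = np.array(cfg.strains)[rng.integers(0, len(cfg.strains), size=n)]
    snvs = pd.DataFrame({
        "snv_id": [f"snv{j:07d}" for j in range(n)],
        "chrom": chrom_arr,
        "pos": pos_arr,
        "ref": _BASES[ref_i],
        "alt": _BASES[alt_i],
        "strain": strain,
        "dhs_id": dhs_assign,
    })

    # --- indels ------------------------------------------------------------
    n_indels = int(round(n * cfg.indel_fraction))
    indels = []
    for _ in range(n_indels):
        c = f"chr{int(rng.integers(0, cfg.n_chroms)) + 1}"
        p = int(rng.integers(0, chrom_len[c]))
        length = int(rng.integers(1, 6)) * (1 if rng.random() < 0.5 else -1)
        indels.append(Indel(chrom=c, pos=p, length=length))

    # --- causal structure ---------------------------------------------------
    n_causal = int(round(n * cfg.fraction_causal))
    causal_idx = rng.choice(n, size=n_causal, replace=False)
    causal = np.zeros(n, dtype=bool)
    causal[causal_idx] = True
    effect = np.zeros(n)
    effect[causal_idx] = (
        rng.uniform(cfg.effect_lo, cfg.effect_hi, size=n_causal)
        * rng.choice([-1.0, 1.0], size=n_causal)
    )
    # which cell types each causal SNV acts in (rows x cell types)
    active = np.zeros((n, n_ct), dtype=bool)
    shared = rng.random(n_causal) < cfg.shared_effect_fraction
    active[causal_idx[shared]] = True
    solo_ct = rng.integers(0, n_ct, size=int((~shared).sum()))
    active[causal_idx[~shared], solo_ct] = True

    # --- motif architecture -------------------------------------------------
    widths = rng.integers(cfg.motif_width_lo, cfg.motif_width_hi + 1, size=cfg.n_motifs)
    motif_rows = []
    for mi in range(cfg.n_motifs):
        w = int(widths[mi])
        core_lo, core_hi = w // 3, w - w // 3  # middle third, half-open
        if rng.random() < cfg.motif_celltype_specific_fraction:
            acts = tuple(sorted(rng.choice(cell_types, size=1, replace=False)))
        else:
            acts = tuple(cell_types)
        motif_rows.append((f"M{mi:03d}", w, core_lo, core_hi, ",".join(acts)))
    motifs = pd.DataFrame(
        motif_rows, columns=["motif_id", "width", "core_start", "core_end", "active_cell_types"]
    )

    match_rows = []
    causal_motif = np.full(n, "", dtype=object)
    causal_position = np.full(n, -1, dtype=np.int64)
    in_motif = rng.random(n_causal) < cfg.fraction_causal_in_motif
    match_id = 0
    for r, put_in_motif in zip(causal_idx, in_motif):
        if not put_in_motif:
            continue
        mi = int(rng.integers(0, cfg.n_motifs))
        m = motifs.iloc[mi]
        core_pos = int(rng.integers(m["core_start"], m["core_end"]))
        strand_m = "+" if rng.random() < 0.5 else "-"
        w = int(m["width"])
        # genome offset g maps to motif position g (+) or w-1-g (-)
        g = core_pos if strand_m == "+" else w - 1 - core_pos
        start = int(pos_arr[r]) - g
        match_rows.append((
            f"match{match_id:07d}", m["motif_id"], chrom_arr[r], start, start + w,
            strand_m, float(rng.normal(14.0, 2.0)),
            float(10.0 ** -rng.uniform(5.5, 8.0)),
            float(10.0 * effect[r] + rng.normal(0.0, 1.0)),
        ))
        match_id += 1
        causal_motif[r] = m["motif_id"]
        causal_position[r] = core_pos
        # cell-type pattern of motif overrides the generic assignment
        acts = m["active_cell_types"].split(",")
        active[r] = False
        active[r, [cell_types.index(a) for a in acts]] = True
    # noise matches over null SNVs (uniform motif position)
    null_rows_sorted = np.flatnonzero(~causal)
    n_noise = int(round(len(null_rows_sorted) * cfg.noise_match_fraction))
    noise_rows = rng.choice(null_rows_sorted, size=n_noise, replace=False)
    noise_motif = rng.integers(0, cfg.n_motifs, size=n_noise)
    for r, mi in zip(noise_rows, noise_motif):
        m = motifs.iloc[int(mi)]
        w = int(m["width"])
        mpos = int(rng.integers(0, w))
        strand_m = "+" if rng.random() < 0.5 else "-"
        g = mpos if strand_m == "+" else w - 1 - mpos
        start = int(pos_arr[r]) - g
        match_rows.append((
            f"match{match_id:07d}", m["motif_id"], chrom_arr[r], start, start + w,
            strand_m, float(rng.normal(11.0, 2.0)),
            float(10.0 ** -rng.uniform(4.0, 6.5)),
            float(rng.normal(0.0, 1.0)),
        ))
        match_id += 1
    motif_matches = pd.DataFrame(
        match_rows,
        columns=["match_id", "motif_id", "chrom", "start", "end", "strand", "score",
                 "pvalue", "logodds_diff"],
    )

    # --- footprints around a fraction of matches ---------------------------
    fp_mask = rng.random(len(motif_matches)) < cfg.footprint_fraction
    fp = motif_matches.loc[fp_mask, ["chrom", "start", "end"]].copy()
    fp["start"] = fp["start"] - 5
    fp["end"] = fp["end"] + 5
    footprints = fp.reset_index(drop=True)

    # --- true effects -------------------------------------------------------
    theta = np.full((n, n_ct), 0.5)
    for ci in range(n_ct):
        theta[:, ci] = np.where(active[:, ci], np.clip(0.5 + effect, 0.02, 0.98), 0.5)
    te = pd.DataFrame({
        "snv_id": [f"snv{j:07d}" for j in range(n)],
        "causal": causal,
        "causal_motif_id": causal_motif,
        "causal_position": causal_position,
        "effect": effect,
    })
    for ci, c in enumerate(cell_types):
        te[f"theta_{c}"] = theta[:, ci]

    # --- allele counts ------------------------------------------------------
    count_frames = []
    strain_sorted = snvs["strain"].to_numpy()
    for s in cfg.strains:
        rows = np.flatnonzero(strain_sorted == s)
        for ci, c in enumerate(cell_types):
            depth = _truncated_nbinom_depth(
                rng, len(rows), cfg.depth_mean, cfg.depth_shape,
                cfg.depth_min, cfg.depth_max,
            )
            th = te[f"theta_{c}"].to_numpy()[rows]
            ref = sample_betabinom(rng, depth, th, cfg.condition_rho(c, s))
            count_frames.append(pd.DataFrame({
                "snv_id": snvs["snv_id"].to_numpy()[rows],
                "condition_id": f"{c}.{s}",
                "ref_count": ref,
                "nonref_count": depth - ref,
            }))
    counts = pd.concat(count_frames, ignore_index=True)

    # --- TSS list -----------------------------------------------------------
    tss_rows = []
    for ci in range(cfg.n_chroms):
        chrom = f"chr{ci + 1}"
        pos = np.sort(rng.integers(0, chrom_len[chrom], size=cfg.n_genes_per_chrom))
        for gi, p in enumerate(pos):
            tss_rows.append((f"gene_{chrom}_{gi:04d}", chrom, int(p),
                             "+" if rng.random() < 0.5 else "-"))
    tss = pd.DataFrame(tss_rows, columns=["gene_id", "chrom", "pos", "strand"])

    # --- annotations + catalog membership -----------------------------------
    causal_sorted = te["causal"].to_numpy()
    effect_sorted = te["effect"].to_numpy()
    nonref_higher = causal_sorted & (effect_sorted < 0)
    base_p = rng.beta(1.0, 3.0, size=n)
    base_p[nonref_higher] = rng.beta(2.0, 2.0, size=int(nonref_higher.sum()))
    membership = rng.random((n, cfg.n_catalogs)) < base_p[:, None]
    mcv = membership.sum(axis=1) / cfg.n_catalogs

    in_dhs = snvs["dhs_id"].to_numpy() >= 0
    dist_tss = np.empty(n, dtype=np.int64)
    for chrom, sub in snvs.groupby("chrom"):
        t = np.sort(tss.loc[tss["chrom"] == chrom, "pos"].to_numpy())
        p = sub["pos"].to_numpy()
        i = np.searchsorted(t, p)
        left = np.abs(p - t[np.clip(i - 1, 0, len(t) - 1)])
        right = np.abs(t[np.clip(i, 0, len(t) - 1)] - p)
        dist_tss[sub.index] = np.minimum(left, right)
    strength = np.where(
        in_dhs, dhs["strength"].to_numpy()[np.clip(snvs["dhs_id"].to_numpy(), 0, None)], 0.0
    )
    width_ann = np.where(
        in_dhs, dhs["width"].to_numpy()[np.clip(snvs["dhs_id"].to_numpy(), 0, None)], 0
    )
    # accessible chromatin buffers strong sites: causal SNVs sit at slightly
    # weaker DHSs and more conserved, footprint-rich positions
    strength = strength * np.where(causal_sorted, 0.8, 1.0)
    conservation = np.clip(
        np.where(causal_sorted, rng.normal(0.7, 0.15, n), rng.normal(0.4, 0.2, n)), 0, 1
    )
    fp_prob = np.where(causal_sorted, 0.7, 0.3)
    footprint_flag = rng.random(n) < fp_prob
    nearby = rng.poisson(np.where(causal_sorted, 3.0, 1.5))
    annotations = pd.DataFrame({
        "snv_id": snvs["snv_id"],
        "mcv": mcv,
        "intron": (rng.random(n) < 0.35),
        "intergenic": ~in_dhs & (rng.random(n) < 0.8),
        "dist_tss": dist_tss,
        "dhs_strength": strength,
        "dhs_width": width_ann,
        "footprint": footprint_flag,
        "nearby_sites": nearby,
        "conservation": conservation,
    })

    return Cohort(
        config=cfg, snvs=snvs, indels=indels, dhs=dhs, motifs=motifs,
        motif_matches=motif_matches, footprints=footprints, true_effects=te,
        counts=counts, annotations=annotations, catalog_membership=membership,
        tss=tss,
    )


# ---------------------------------------------------------------------------
# read-level fixtures


@dataclass(frozen=True)
class SyntheticReadRecord:
    """A minimal aligned-read record carrying its own ground-truth label.

    `bases`/`quals` cover positions start..start+length-1 on the
    reference (1:1 alignment; indel-containing alignments are not
    simulated). `truth` is the filter outcome the counting pipeline is
    expected to assign to this read at the focal SNV.
    """

    chrom: str
    start: int
    length: int
    strand: str
    mapq: int
    tlen: int
    bases: str
    quals: tuple
    mate_id: str
    read_id: str
    maps_both: bool = True
    extra_mismatches: int = 0
    duplicate_of: str | None = None
    truth: str = PASS

    def __post_init__(self):
        if self.length <= 0:
            raise ValueError("read length must be positive")
        if any(q < 0 or q > 60 for q in self.quals):
            raise ValueError("base qualities must lie in [0, 60]")

    @property
    def end(self) -> int:
        return self.start + self.length

    def base_at(self, pos: int) -> str:
        return self.bases[pos - self.start]

    def qual_at(self, pos: int) -> int:
        return self.quals[pos - self.start]

    def five_prime_offset(self, pos: int) -> int:
        """Offset of pos from the read's 5' end, in read orientation."""
        if self.strand == "-":
            return self.end - 1 - pos
        return pos - self.start


def _mk_read(snv: SNV, *, offset: int = 20, length: int = 36, strand: str = "+",
             mapq: int = 60, tlen: int = 200, qual: int = 30, base: str | None = None,
             mate_id: str, read_id: str, maps_both: bool = True,
             extra_mismatches: int = 0, truth: str = PASS,
             start: int | None = None) -> SyntheticReadRecord:
    """Place a read so the SNV sits `offset` bases from its 5' end."""
    if start is None:
        start = snv.pos - offset if strand == "+" else snv.pos + offset - (length - 1)
    idx = snv.pos - start
    if not 0 <= idx < length:
        raise ValueError("SNV does not fall inside the read")
    bases = ["A"] * length
    bases[idx] = base if base is not None else snv.ref_allele
    quals = [30] * length
    quals[idx] = qual
    return SyntheticReadRecord(
        chrom=snv.chrom, start=start, length=length, strand=strand, mapq=mapq,
        tlen=tlen, bases="".join(bases), quals=tuple(quals), mate_id=mate_id,
        read_id=read_id, maps_both=maps_both, extra_mismatches=extra_mismatches,
        truth=truth,
    )


def simulate_reads_at_snv(snv: SNV, n_reads: int, scenario: str = "clean",
                          seed: int = 0) -> list[SyntheticReadRecord]:
    """Labeled read fixtures exercising each counting filter.

    Scenarios:
      clean                all pass, alternating ref/alt
      low_baseq            variant base quality 20 (boundary fail) vs 21+
      five_prime_offsets   variant at 5' offsets 0..n-1; 0-2 fail
      five_prime_minus     same, on minus-strand reads
      duplicates           n reads share one 5' position; exactly 1 passes
      mismatches           extra mismatches 0..n-1; >2 fail
      template_len         template lengths straddling 500 bp
      mapq                 mapping qualities straddling 20
      genome_discordant    reads not mapping to both genomes
      allele_other         base at SNV neither ref nor alt
      pair                 proper pairs, both mates covering the SNV
    """
    if n_reads < 0:
        raise ValueError("n_reads must be non-negative")
    rng = np.random.default_rng(seed)
    reads: list[SyntheticReadRecord] = []
    if scenario == "clean":
        for i in range(n_reads):
            base = snv.ref_allele if i % 2 == 0 else snv.alt_allele
            reads.append(_mk_read(snv, offset=5 + i, base=base,
                                  mate_id=f"f{i}", read_id=f"r{i}"))
    elif scenario == "low_baseq":
        for i in range(n_reads):
            q = 20 if i % 2 == 0 else 21  # >20 required, so 20 fails
            reads.append(_mk_read(snv, offset=5 + i, qual=q,
                                  mate_id=f"f{i}", read_id=f"r{i}",
                                  truth=LOW_BASEQ if q <= 20 else PASS))
    elif scenario == "five_prime_offsets":
        for off in range(n_reads):
            reads.append(_mk_read(snv, offset=off, mate_id=f"f{off}",
                                  read_id=f"r{off}",
                                  truth=FIVE_PRIME if off < 3 else PASS))
    elif scenario == "five_prime_minus":
        for off in range(n_reads):
            reads.append(_mk_read(snv, offset=off, strand="-", mate_id=f"f{off}",
                                  read_id=f"r{off}",
                                  truth=FIVE_PRIME if off < 3 else PASS))
    elif scenario == "duplicates":
        for i in range(n_reads):
            reads.append(_mk_read(snv, offset=10, mate_id=f"f{i}", read_id=f"r{i}",
                                  qual=30 if i == 0 else 25,
                                  truth=PASS if i == 0 else DUPLICATE))
    elif scenario == "mismatches":
        for i in range(n_reads):
            reads.append(_mk_read(snv, offset=5 + i, extra_mismatches=i,
                                  mate_id=f"f{i}", read_id=f"r{i}",
                                  truth=MISMATCHES if i > 2 else PASS))
    elif scenario == "template_len":
        for i in range(n_reads):
            t = 499 if i % 2 == 0 else 500  # < 500 required
            reads.append(_mk_read(snv, offset=5 + i, tlen=t,
                                  mate_id=f"f{i}", read_id=f"r{i}",
                                  truth=PASS if t < 500 else TEMPLATE_LEN))
    elif scenario == "mapq":
        for i in range(n_reads):
            mq = 19 if i % 2 == 0 else 20  # >= 20 required
            reads.append(_mk_read(snv, offset=5 + i, mapq=mq,
                                  mate_id=f"f{i}", read_id=f"r{i}",
                                  truth=MAPQ if mq < 20 else PASS))
    elif scenario == "genome_discordant":
        for i in range(n_reads):
            ok = i % 2 == 1
            reads.append(_mk_read(snv, offset=5 + i, maps_both=ok,
                                  mate_id=f"f{i}", read_id=f"r{i}",
                                  truth=PASS if ok else GENOME_DISCORDANT))
    elif scenario == "allele_other":
        other = next(b for b in "ACGT" if b not in (snv.ref_allele, snv.alt_allele))
        for i in range(n_reads):
            reads.append(_mk_read(snv, offset=5 + i, base=other,
                                  mate_id=f"f{i}", read_id=f"r{i}",
                                  truth=ALLELE_OTHER))
    elif scenario == "pair":
        for i in range(n_reads // 2):
            reads.append(_mk_read(snv, offset=5 + i, qual=31, mate_id=f"f{i}",
                                  read_id=f"r{i}a", truth=PASS))
            reads.append(_mk_read(snv, offset=8 + i, strand="-", mate_id=f"f{i}",
                                  read_id=f"r{i}b", truth=PAIR_ALREADY_COUNTED))
    else:
        raise ValueError(f"unknown scenario {scenario!r}")
    return reads


def reads_to_sam_text(reads: list[SyntheticReadRecord],
                      chrom_lengths: dict[str, int] | None = None) -> str:
    """Render read records as minimal SAM text (for integration tests).

    Non-standard record state travels in optional tags: NM (mismatches
    beyond the known variant), XB (maps to both genomes), XT (the
    ground-truth filter label). POS is 1-based per SAM.
    """
    if chrom_lengths is None:
        chrom_lengths = {}
        for r in reads:
            chrom_lengths[r.chrom] = max(chrom_lengths.get(r.chrom, 0),
                                         r.end + 1000)
    lines = ["@HD\tVN:1.6\tSO:unknown"]
    for chrom in sorted(chrom_lengths):
        lines.append(f"@SQ\tSN:{chrom}\tLN:{chrom_lengths[chrom]}")
    for r in reads:
        flag = 16 if r.strand == "-" else 0
        qual = "".join(chr(q + 33) for q in r.quals)
        lines.append("\t".join([
            r.read_id, str(flag), r.chrom, str(r.start + 1), str(r.mapq),
            f"{r.length}M", "*", "0", str(r.tlen), r.bases, qual,
            f"NM:i:{r.extra_mismatches}", f"XB:i:{int(r.maps_both)}",
            f"XM:Z:{r.mate_id}", f"XT:Z:{r.truth}",
        ]))
    return "\n".join(lines) + "\n"


def reads_from_sam_text(text: str) -> list[SyntheticReadRecord]:
    """Parse the minimal SAM dialect written by reads_to_sam_text."""
    reads = []
    for line in text.splitlines():
        if not line or line.startswith("@"):
            continue
        f = line.split("\t")
        tags = dict(t.split(":", 2)[::2] for t in f[11:])
        quals = tuple(ord(c) - 33 for c in f[10])
        reads.append(SyntheticReadRecord(
            chrom=f[2], start=int(f[3]) - 1, length=len(f[9]),
            strand="-" if int(f[1]) & 16 else "+", mapq=int(f[4]),
            tlen=int(f[8]), bases=f[9], quals=quals,
            mate_id=tags.get("XM", f[0]), read_id=f[0],
            maps_both=bool(int(tags.get("XB", "1"))),
            extra_mismatches=int(tags.get("NM", "0")),
            truth=tags.get("XT", PASS),
        ))
    return reads


# ---------------------------------------------------------------------------
# mappability and expression coupling


def simulate_mappability(snvs: pd.DataFrame, mappable_fraction=1.0,
                         seed: int = 0, fraction_low: float = 0.0) -> pd.DataFrame:
    """Per-SNV mappable fractions (in-silico read remapping surrogate).

    `mappable_fraction` may be a scalar applied to every SNV or an array.
    With `fraction_low` > 0, that share of SNVs instead draws a fraction
    uniform in [0.5, 0.95] (i.e. failing the > 0.95 retention rule).
    """
    rng = np.random.default_rng(seed)
    n = len(snvs)
    frac = np.broadcast_to(np.asarray(mappable_fraction, dtype=float), (n,)).copy()
    if np.any((frac < 0) | (frac > 1)):
        raise ValueError("mappable fractions must lie in [0, 1]")
    if fraction_low > 0:
        low = rng.random(n) < fraction_low
        frac[low] = rng.uniform(0.5, 0.95, size=int(low.sum()))
    return pd.DataFrame({"snv_id": snvs["snv_id"], "mappable_fraction": frac})


def exponential_kernel(scale_bp: float):
    """Distance -> coupling weight, exp(-|d|/scale); monotone non-increasing."""
    def k(dist):
        return np.exp(-np.abs(np.asarray(dist, dtype=float)) / scale_bp)
    return k


def simulate_linked_expression(cohort: Cohort, kernel, seed: int,
                               noise_sd: float = 0.05, depth_mean: float = 200.0,
                               max_distance: int = 500_000,
                               rho: float | None = None) -> pd.DataFrame:
    """Transcript allele counts coupled to nearby DHS allelic ratios.

    Each transcript's true allelic ratio is the kernel-weighted mix of the
    true ratios of DHSs within `max_distance` of its TSS, plus independent
    Gaussian noise; counts are then drawn beta-binomially per cell-type
    condition. A kernel that is identically zero decouples transcripts
    from accessibility entirely.
    """
    cfg = cohort.config
    rng = np.random.default_rng(seed)
    rho = cfg.rho if rho is None else rho
    # per-DHS true theta per cell type: mean effect over its causal SNVs
    te = cohort.true_effects.merge(cohort.snvs[["snv_id", "dhs_id"]], on="snv_id")
    dhs_theta = {}
    for c in cfg.cell_types:
        g = te[te["dhs_id"] >= 0].groupby("dhs_id")[f"theta_{c}"].mean()
        dhs_theta[c] = g
    dhs_mid = ((cohort.dhs["start"] + cohort.dhs["end"]) // 2).to_numpy()
    dhs_chrom = cohort.dhs["chrom"].to_numpy()
    dhs_ids = cohort.dhs["dhs_id"].to_numpy()

    rows = []
    any_pair = False
    for t in cohort.tss.itertuples(index=False):
        on_chrom = dhs_chrom == t.chrom
        d = np.abs(dhs_mid[on_chrom] - t.pos)
        near = d <= max_distance
        ids = dhs_ids[on_chrom][near]
        w = np.asarray(kernel(d[near]), dtype=float)
        for c in cfg.cell_types:
            th = dhs_theta[c].reindex(ids).fillna(0.5).to_numpy()
            if w.sum() > 0:
                any_pair = True
                mix = float(np.sum(w * th) / np.sum(w))
            else:
                mix = 0.5
            theta_t = float(np.clip(mix + rng.normal(0.0, noise_sd), 0.02, 0.98))
            depth = int(_truncated_nbinom_depth(
                rng, np.array([1]), depth_mean, 2.0, 10, 5000)[0])
            ref = int(sample_betabinom(rng, np.array([depth]),
                                       np.array([theta_t]), rho)[0])
            rows.append((t.gene_id, f"{c}", ref, depth - ref))
    if not any_pair:
        import warnings
        warnings.warn("no TSS within range of any DHS; transcripts are independent")
    return pd.DataFrame(rows, columns=["transcript_id", "condition_id",
                                       "ref_count", "nonref_count"])
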