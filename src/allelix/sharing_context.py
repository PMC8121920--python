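"""Cross-condition sharing, spatial correlation, and activity spectra.

Sharing between two conditions is quantified as 1 - pi0 of one
condition's p-values restricted to the SNVs the other condition flagged
imbalanced (Storey's estimator of the non-null fraction). Spatial
resolution is assessed by the Pearson correlation of allelic ratios at
consecutive tested SNVs binned by distance, against a permutation band.
The activity spectrum stratifies SNV classes by their cell-type activity
(MCV: fraction of reference DHS catalogs containing the site).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .imbalance import storey_pi0

__all__ = [
    "pairwise_sharing",
    "mean_sharing_by_relationship",
    "adjacent_ratio_correlation",
    "activity_spectrum",
    "DEFAULT_DISTANCE_BINS",
]

DEFAULT_DISTANCE_BINS = (0, 50, 100, 250, 500, 1_000, 2_500, 5_000, 10_000)


def pairwise_sharing(calls: pd.DataFrame, min_snvs: int = 50) -> pd.DataFrame:
    """Square sharing matrix over conditions.

    `calls` is a per-condition call table (columns snv_id, group_id,
    p_value, imbalanced). Entry (A, B) = 1 - pi0 of B's p-values over the
    SNVs flagged in A, computed on the intersection of the two tested
    universes; entries resting on fewer than `min_snvs` SNVs are NaN.
    """
    conditions = sorted(calls["group_id"].unique())
    by_cond = {g: sub.set_index("snv_id") for g, sub in calls.groupby("group_id")}
    mat = pd.DataFrame(np.nan, index=conditions, columns=conditions)
    counts = pd.DataFrame(0, index=conditions, columns=conditions)
    for a in conditions:
        flagged_a = by_cond[a].index[by_cond[a]["imbalanced"]]
        for b in conditions:
            common = flagged_a.intersection(by_cond[b].index)
            counts.loc[a, b] = len(common)
            if len(common) < min_snvs:
                continue
            p_b = by_cond[b].loc[common, "p_value"].to_numpy()
            mat.loc[a, b] = float(np.clip(1.0 - storey_pi0(p_b), 0.0, 1.0))
    mat.attrs["n_snvs"] = counts
    return mat


def mean_sharing_by_relationship(sharing: pd.DataFrame, scheme: pd.DataFrame
                                 ) -> pd.DataFrame:
    """Mean and SD of sharing over ordered sample pairs by relationship.

    Relationship classes: same cell type (any strain), same strain only,
    unrelated (neither shared). Self-pairs are excluded. `scheme` has
    columns sample_id, cell_type, strain. A class with fewer than two
    values reports NaN SD.
    """
    meta = scheme.set_index("sample_id")
    buckets: dict[str, list[float]] = {
        "same_cell_type": [], "same_strain_only": [], "unrelated": []}
    for a in sharing.index:
        for b in sharing.columns:
            if a == b:
                continue
            v = sharing.loc[a, b]
            if np.isnan(v):
                continue
            same_ct = meta.loc[a, "cell_type"] == meta.loc[b, "cell_type"]
            same_strain = meta.loc[a, "strain"] == meta.loc[b, "strain"]
            if same_ct:
                buckets["same_cell_type"].append(v)
            elif same_strain:
                buckets["same_strain_only"].append(v)
            else:
                buckets["unrelated"].append(v)
    rows = []
    for rel, vals in buckets.items():
        arr = np.asarray(vals)
        rows.append((
            rel,
            float(arr.mean()) if arr.size else np.nan,
            float(arr.std(ddof=1)) if arr.size > 1 else np.nan,
            arr.size,
        ))
    return pd.DataFrame(rows, columns=["relationship", "mean", "sd", "n_pairs"])


@dataclass
class DistanceCorrelationCurve:
    bin_edges: np.ndarray
    r: np.ndarray            # NaN where masked
    n_pairs: np.ndarray
    band_lo: np.ndarray
    band_hi: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "bin_lo": self.bin_edges[:-1], "bin_hi": self.bin_edges[1:],
            "r": self.r, "n_pairs": self.n_pairs,
            "band_lo": self.band_lo, "band_hi": self.band_hi,
        })


def _binned_pearson(d, x, y, edges, min_pairs):
    r = np.full(len(edges) - 1, np.nan)
    n = np.zeros(len(edges) - 1, dtype=int)
    which = np.digitize(d, edges) - 1
    for b in range(len(edges) - 1):
        sel = which == b
        n[b] = int(sel.sum())
        if n[b] < min_pairs:
            continue
        xs, ys = x[sel], y[sel]
        if xs.std() == 0 or ys.std() == 0:
            continue
        r[b] = float(np.corrcoef(xs, ys)[0, 1])
    return r, n


def adjacent_ratio_correlation(calls: pd.DataFrame, positions: pd.DataFrame,
                               bin_edges=DEFAULT_DISTANCE_BINS,
                               min_pairs: int = 10, n_perm: int = 200,
                               seed: int = 0) -> DistanceCorrelationCurve:
    """Correlation of allelic ratios at consecutive tested SNVs by distance.

    Each tested SNV within one condition is paired with its immediate
    downstream tested neighbor on the same chromosome; pairs are binned
    by genomic distance. The 95% band comes from shuffling ratios among
    tested SNVs within each condition (`n_perm` permutations).
    `positions` has columns snv_id, chrom, pos.
    """
    edges = np.asarray(bin_edges)
    rng = np.random.default_rng(seed)
    df = calls.merge(positions, on="snv_id")
    dists, xs, ys, cond_of_pair = [], [], [], []
    for (gid, chrom), sub in df.groupby(["group_id", "chrom"]):
        sub = sub.sort_values("pos")
        p = sub["pos"].to_numpy()
        ratio = sub["allelic_ratio"].to_numpy()
        if len(p) < 2:
            continue
        dists.append(p[1:] - p[:-1])
        xs.append(ratio[:-1])
        ys.append(ratio[1:])
        cond_of_pair.append(np.full(len(p) - 1, str(gid)))
    if not dists:
        empty = np.full(len(edges) - 1, np.nan)
        return DistanceCorrelationCurve(edges, empty, np.zeros(len(edges) - 1, int),
                                        empty.copy(), empty.copy())
    d = np.concatenate(dists)
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    r, n = _binned_pearson(d, x, y, edges, min_pairs)

    # permutation band: shuffle ratios among tested SNVs within condition,
    # keeping positions fixed, then re-form the same neighbor pairs
    perm_r = np.full((n_perm, len(edges) - 1), np.nan)
    layout = []  # (ratio vector, per-chrom row slices, per-chrom distances)
    for gid, sub in df.groupby("group_id"):
        sub = sub.sort_values(["chrom", "pos"]).reset_index(drop=True)
        chrom_slices = []
        for chrom, csub in sub.groupby("chrom"):
            rows = csub.index.to_numpy()
            if len(rows) < 2:
                continue
            p = csub["pos"].to_numpy()
            chrom_slices.append((rows, p[1:] - p[:-1]))
        layout.append((sub["allelic_ratio"].to_numpy(), chrom_slices))
    for it in range(n_perm):
        xp, yp, dp = [], [], []
        for ratios, chrom_slices in layout:
            vals = rng.permutation(ratios)
            for rows, dd in chrom_slices:
                v = vals[rows]
                dp.append(dd)
                xp.append(v[:-1])
                yp.append(v[1:])
        if not dp:
            continue
        rp, _ = _binned_pearson(np.concatenate(dp), np.concatenate(xp),
                                np.concatenate(yp), edges, min_pairs)
        perm_r[it] = rp
    import warnings as _warnings
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN bins
        lo = np.nanpercentile(perm_r, 2.5, axis=0)
        hi = np.nanpercentile(perm_r, 97.5, axis=0)
    return DistanceCorrelationCurve(edges, r, n, lo, hi)


def activity_spectrum(classes: pd.DataFrame, catalog_membership: pd.DataFrame
                      ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cell-type activity (MCV) distribution per SNV class.

    `classes` maps snv_id -> class in {ref_higher, nonref_higher,
    not_imbalanced, not_tested}; `catalog_membership` is long-form
    (snv_id, catalog_id, present). Returns (cdf, overlap) where `cdf`
    gives per-class cumulative fractions over the MCV grid and `overlap`
    the per-(class, catalog) overlap proportion.
    """
    wide = (catalog_membership.pivot_table(index="snv_id", columns="catalog_id",
                                           values="present", fill_value=False)
            .astype(bool))
    n_cat = wide.shape[1]
    mcv = wide.sum(axis=1) / n_cat
    df = classes.merge(mcv.rename("mcv"), left_on="snv_id", right_index=True,
                       how="left").fillna({"mcv": 0.0})
    grid = np.arange(0, n_cat + 1) / n_cat
    cdf_rows = []
    for cls, sub in df.groupby("snv_class"):
        vals = sub["mcv"].to_numpy()
        for g in grid:
            cdf_rows.append((cls, g, float((vals <= g).mean())))
    cdf = pd.DataFrame(cdf_rows, columns=["snv_class", "mcv", "cum_fraction"])

    overlap_rows = []
    for cls, sub in df.groupby("snv_class"):
        ids = sub["snv_id"]
        present = wide.reindex(ids).fillna(False)
        for cat in wide.columns:
            overlap_rows.append((cls, cat, float(present[cat].mean())))
    overlap = pd.DataFrame(overlap_rows, columns=["snv_class", "catalog_id", "proportion"])
    return cdf, overlap
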