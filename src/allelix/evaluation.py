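"""Ground-truth evaluation utilities for synthetic cohorts."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .imbalance import (CallThresholds, PoolingScheme, call_imbalance,
                        fit_all_nulls, pool_counts)
from .synthetic_data import Cohort, SimConfig, simulate_cohort


def call_cohort(cohort: Cohort, level: str = "cell_type",
                thresholds: CallThresholds = CallThresholds()) -> pd.DataFrame:
    """Pool, fit per-condition nulls, and call imbalance on one cohort."""
    scheme = PoolingScheme.from_frame(cohort.scheme_frame())
    pooled = pool_counts(cohort.counts, scheme, level)
    nulls = fit_all_nulls(pooled, fallback_rho=cohort.config.rho)
    return call_imbalance(pooled, nulls, thresholds, level)


def false_discovery_proportion(cohort: Cohort, calls: pd.DataFrame) -> tuple[int, int]:
    """(false positives, total flagged): a flag is false when the SNV's
    true allelic ratio is 0.5 in every condition."""
    causal = cohort.true_effects.set_index("snv_id")["causal"]
    flagged = calls.loc[calls["imbalanced"], "snv_id"]
    if flagged.empty:
        return 0, 0
    fp = int((~causal.loc[flagged]).sum())
    return fp, int(len(flagged))


CELLTYPE_ARCHITECTURE = dict(
    n_snvs=12_000, fraction_causal=0.15, motif_celltype_specific_fraction=1.0,
    shared_effect_fraction=0.0, fraction_causal_in_motif=0.9,
    depth_mean=150.0, effect_lo=0.2, noise_match_fraction=0.15,
)


def compare_celltype_vs_aggregate(seed: int) -> tuple[float, float]:
    """(AUPR cell-type-gated, AUPR aggregate) at predicting one cell
    type's imbalance on a held-out SNV split of a cohort whose causal
    motifs are each active in a single cell type."""
    from .cato2 import (gated_tf_labels, precision_recall, score_variants,
                        train_bundle)
    from .motif_profiles import snv_motif_assignments

    cohort = simulate_cohort(SimConfig(seed=seed, **CELLTYPE_ARCHITECTURE))
    calls = call_cohort(cohort, level="cell_type")
    assigns = snv_motif_assignments(cohort.snvs, cohort.motif_matches)
    calls_by_ct = {ct: sub for ct, sub in calls.groupby("group_id")}
    target_ct = cohort.config.cell_types[0]
    ids = cohort.annotations["snv_id"].to_numpy()
    rng = np.random.default_rng(seed)
    held_mask = rng.random(len(ids)) < 0.5
    train_ids = set(ids[~held_mask])
    held_ids = set(ids[held_mask])

    def tr(df):
        return df[df["snv_id"].isin(train_ids)]

    cbc_tr = {ct: tr(sub) for ct, sub in calls_by_ct.items()}
    target = cbc_tr[target_ct].groupby("snv_id")["imbalanced"].any()
    agg_labels = tr(calls).groupby("snv_id")["imbalanced"].any()
    tf_lab = gated_tf_labels(tr(assigns), cohort.snvs, cbc_tr, cohort.motifs)
    b_ct = train_bundle(tr(cohort.annotations), tr(assigns), target,
                        tf_labels=tf_lab, seed=seed, folds=5, min_tf_rows=25)
    b_agg = train_bundle(tr(cohort.annotations), tr(assigns), agg_labels,
                         seed=seed, folds=5, min_tf_rows=25)

    ann_h = cohort.annotations[cohort.annotations["snv_id"].isin(held_ids)]
    assigns_h = assigns[assigns["snv_id"].isin(held_ids)]
    tsub = calls_by_ct[target_ct]
    truth = (tsub[tsub["snv_id"].isin(held_ids)]
             .groupby("snv_id")["imbalanced"].any())
    s_ct = score_variants(b_ct, ann_h, assigns_h)
    s_agg = score_variants(b_agg, ann_h, assigns_h)
    y = truth.reindex(s_ct["snv_id"]).fillna(False).to_numpy()
    _, a_ct = precision_recall(s_ct["score"].to_numpy(), y)
    _, a_agg = precision_recall(s_agg["score"].to_numpy(), y)
    return a_ct, a_agg


def realized_fdr_percent(seeds, n_snvs: int = 50_000, level: str = "cell_type",
                         **sim_kwargs) -> tuple[float, int, int]:
    """Mean realized false-discovery proportion over seeds, in percent.

    Returns (mean FDP * 100, total false positives, total flagged).
    """
    fdps = []
    tot_fp = tot_flag = 0
    for seed in seeds:
        cohort = simulate_cohort(SimConfig(seed=int(seed), n_snvs=n_snvs,
                                           **sim_kwargs))
        calls = call_cohort(cohort, level=level)
        fp, flagged = false_discovery_proportion(cohort, calls)
        tot_fp += fp
        tot_flag += flagged
        fdps.append(fp / flagged if flagged else 0.0)
    return 100.0 * float(np.mean(fdps)), tot_fp, tot_flag
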