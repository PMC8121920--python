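"""Correlate allelic accessibility with allelic transcript levels.

Transcript allele counts are coupled to nearby DHS effects through an
exponential kernel with a 10 kb scale; the distance-binned Pearson
correlation between DHS and transcript allelic ratios should exceed a
permutation null band only near the TSS and decay with distance.
"""

import pandas as pd

from allelix.expression_link import (TranscriptModel, call_rna_imbalance,
                                     distance_binned_correlation,
                                     pair_dhs_tss, permutation_band)
from allelix.synthetic_data import (SimConfig, exponential_kernel,
                                    simulate_cohort,
                                    simulate_linked_expression)

cohort = simulate_cohort(SimConfig(seed=5, n_snvs=12_000, fraction_causal=0.4,
                                   shared_effect_fraction=1.0,
                                   n_genes_per_chrom=400,
                                   dhs_gap_mean=20_000.0))
rna = simulate_linked_expression(cohort, exponential_kernel(10_000), seed=6,
                                 noise_sd=0.03, depth_mean=300)
rna_calls = call_rna_imbalance(rna, fallback_rho=cohort.config.rho)

# accessibility side: true per-DHS allelic ratios per cell type
te = cohort.true_effects.merge(cohort.snvs[["snv_id", "dhs_id"]], on="snv_id")
rows = []
dhs = cohort.dhs.set_index("dhs_id")
for ct in cohort.config.cell_types:
    g = te[te["dhs_id"] >= 0].groupby("dhs_id")[f"theta_{ct}"].mean()
    for did, th in g.items():
        rows.append((f"d{did}", dhs.loc[did, "chrom"],
                     (dhs.loc[did, "start"] + dhs.loc[did, "end"]) // 2, ct, th))
dhs_ratios = pd.DataFrame(rows, columns=["dhs_id", "chrom", "midpoint",
                                         "condition_id", "allelic_ratio"])
transcripts = [TranscriptModel(t.gene_id, t.chrom, t.pos, t.pos + 100,
                               t.strand, ())
               for t in cohort.tss.itertuples(index=False)]

pairs = pair_dhs_tss(dhs_ratios, rna_calls, transcripts)
curve = distance_binned_correlation(pairs, min_pairs=30)
band = permutation_band(pairs, n_perm=200, seed=7, min_pairs=30)
out = curve.merge(band, on=["bin_lo", "bin_hi"])

print(f"{len(pairs)} DHS-TSS pairs within 500 kb")
print("signed-distance bin        r      95% null band")
for r in out.itertuples(index=False):
    if r.n_pairs == 0:
        continue
    mark = " *" if r.r > r.band_hi or r.r < r.band_lo else ""
    print(f"  {r.bin_lo:>8} .. {r.bin_hi:>8}  {r.r:+.3f}  "
          f"[{r.band_lo:+.3f}, {r.band_hi:+.3f}]{mark}")
# Bins marked * exit the permutation band: correlation is concentrated
# within ~10 kb of the TSS, mirroring the kernel scale that generated it.
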