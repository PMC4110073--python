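"""Validate NMD predictions against carrier expression levels.

Generates an expression matrix in which carriers of NMD-target variants have
the affected gene's expression halved, standardizes per gene, and compares
average carrier z-scores between NMD-target and NMD-escape variants with a
one-sided Wilcoxon rank-sum test, plus the score-vs-expression quintile view.
"""
import numpy as np

import truncscore as ts
from truncscore import classifier as nb
from truncscore import expression as ex

cfg = ts.FixtureConfig(seed=11)  # nmd_effect_size = 0.5
genes, domain_df, _ = ts.generate_gene_models(cfg)
variants, truth = ts.generate_variants(cfg, genes, domain_df)
em = ts.generate_expression(cfg, genes, variants, truth)

zm = ts.zscore_by_gene(em)
tab = ts.variant_z_table(
    variants, zm, dict(zip(truth.variant_id, truth.gene_id))
).set_index("variant_id")
nmd = truth.set_index("variant_id").nmd_target.astype(bool).reindex(tab.index)

z_target = tab.mean_carrier_z[nmd].to_numpy()
z_escape = tab.mean_carrier_z[~nmd].to_numpy()
p = ex.compare_groups(z_target, z_escape, "less")
print(f"median carrier z | NMD target ({len(z_target)} variants): {np.median(z_target):+.2f}")
print(f"median carrier z | NMD escape ({len(z_escape)} variants): {np.median(z_escape):+.2f}")
print(f"one-sided rank-sum p (target < escape): {p:.2e}")

# correlate the pathogenicity ranking with expression impact
domains = [
    ts.DomainAnnotation(r.transcript_id, r.domain_id, int(r.start_aa), int(r.end_aa))
    for r in domain_df.itertuples()
]
table = nb.feature_frame(ts.annotate_variants(variants, genes, domains))
labels = truth.set_index("variant_id").loc[table.variant_id, "label"].to_numpy()
params = nb.fit(nb.TrainingSet(table[list(nb.FEATURE_NAMES)].to_numpy(), labels))
scored = nb.score_variants(table, params).set_index("variant_id")
rank_pct = ts.rank_percentile(scored.loc[tab.index, "posterior"].to_numpy())

summary, rho = ex.score_expression_quintiles(rank_pct, tab.mean_carrier_z.to_numpy())
print(f"\nSpearman rho, carrier z vs score rank percentile: {rho:.2f}")
print(summary.to_string(index=False))
# Carriers of NMD-target variants show clearly reduced expression of the
# affected gene; quintile 1 (strongest decrease) holds the most pathogenic
# rank percentiles, so rho is positive.
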