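"""Order samples along the malignant continuum and find trending genes.

Per sample, the target subtype's cells are tested against pooled
normal-sample cells with the two-part hurdle test; the per-sample log2FC
profiles of recurrently significant genes are decomposed by PCA, a
principal curve is fitted in the PC1-PC2 plane, and each sample's
arc-length position on that curve is its place on the continuum from
normal tissue to cancer.
"""

from scipy.stats import spearmanr

from serrapath import (
    SimConfig,
    gene_trends,
    generate_dataset,
    normalize,
    order_samples,
    profile_all_samples,
)

dataset, truth = generate_dataset(SimConfig(seed=1))
norm = normalize(dataset)

profile = profile_all_samples(norm, target_subtype="SLC1", reference_stage="normal")
stages = dataset.cells.drop_duplicates("sample_id").set_index("sample_id")["stage"]
result = order_samples(profile, stages)

print(f"selected genes (significant in >= 2 samples): {len(result.selected_genes)}")
print(f"explained variance PC1/PC2: "
      f"{result.explained_variance[0]:.2f} / {result.explained_variance[1]:.2f}")

print("\nsample ordering along the continuum (position 0 = normal-like):")
for sample, pos in sorted(result.position.items(), key=lambda kv: kv[1]):
    print(f"  {sample:10s} {stages[sample]:7s} position {pos:.3f}  "
          f"planted s {truth.s_true[sample]:.2f}")

ids = list(result.position)
rho, _ = spearmanr([result.position[s] for s in ids], [truth.s_true[s] for s in ids])
print(f"\nSpearman(recovered position, planted score) = {rho:.3f}")
# |rho| near 1 means the expression-only ordering reproduces the planted
# biological progression of the cohort.

# Trend axis: the study data put the progression signal on PC2, so that is
# the default axis; in this simulation the continuum dominates PC1 (90% of
# the variance), so we correlate against the arc-length positions instead.
import pandas as pd

trends = gene_trends(
    profile, pd.Series(result.position), genes=result.selected_genes
)
top = trends.dropna().reindex(
    trends["spearman_rho"].abs().sort_values(ascending=False).index
).head(5)
print("\nstrongest gene trends along the continuum (rho, BH-adjusted p):")
for _, row in top.iterrows():
    print(f"  {row['gene']}: rho={row['spearman_rho']:+.2f}, p_adj={row['p_adj']:.2e}")
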