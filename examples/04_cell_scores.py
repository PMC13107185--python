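"""Per-sample signature scoring (ssGSEA-style) and aggregate
immune/stroma scores.

Signatures are rank-based running-sum enrichment scores per sample, so any
monotone rescaling of a sample's values leaves them unchanged.  Here the
planted immune signature tracks the NAT subtype, and the aggregate
ImmuneScore separates the two subtypes.
"""

from scipy.stats import mannwhitneyu

from escctraj import (SimConfig, aggregate_scores, correlate_scores,
                      generate_cohort, ssgsea_score)
from escctraj.simulate import make_signature_sets

matrix, meta, clinical, truth = generate_cohort(SimConfig(seed=1))
sets = make_signature_sets(truth)
nat = matrix.subset_samples(meta.loc[meta.tissue == "NAT", "sample_id"])

scores = ssgsea_score(nat, sets, weight=0.25)
print("signature score matrix:", scores.scores.shape,
      "(signatures x NAT samples)")

agg = aggregate_scores(scores, immune_sets=["immune_cells"],
                       stroma_sets=["stroma_cells"])
sub = truth.subtype_label.loc[
    meta.set_index("sample_id").loc[agg.index, "patient_id"]].to_numpy()
imm = agg["ImmuneScore"]
p = mannwhitneyu(imm[sub == 2], imm[sub == 1], alternative="greater").pvalue
print(f"ImmuneScore subtype-2 vs subtype-1 (one-sided rank-sum): p = {p:.2e}")
print("  -> the planted immune-rich subtype is recovered by the scores")

corr = correlate_scores(scores, scores)
pair = corr[(corr.set_a == "immune_cells") & (corr.set_b == "stroma_cells")]
print(f"Spearman rho immune vs stroma scores: {pair['rho'].iloc[0]:.2f}")
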