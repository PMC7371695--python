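"""Spike-anchored translation efficiency and global-shift detection.

Simulates matched footprint/RNA libraries (3 animals per genotype,
Drosophila spike panel at 1/15) in which the knockout's footprint counts
carry a genome-wide 0.87x scale factor, then recovers that global shift —
the signal conventional normalization would erase.
"""

from pol3kit.ribo import differential_te, global_te_shift, te_pipeline
from pol3kit.simulate import simulate_ribo

# study-design defaults plus 5% of genes with an extra gene-specific TE loss
data, truth = simulate_ribo(seed=21, de_fraction=0.05, te_effect=-1.0)
te, corrections = te_pipeline(
    data["rf_counts"], data["rna_counts"], data["gene_map"], data["spike_ids"]
)
shift = global_te_shift(te, data["groups"])
diff = differential_te(te, data["groups"])

print(f"per-sample spike correction factors (log2):\n{corrections.round(3)}")
print(f"global TE shift: {shift['mean_shift_log2']:.3f} log2 "
      f"= {shift['percent_change']:.1f}% "
      "(truth: 0.87x globally, plus the gene-specific losses)")
print(f"KS D = {shift['ks_d']:.3f}, p = {shift['ks_p']:.2e}")
print(f"differential TE: {int(diff['significant_05'].sum())} genes at adj-p <= 0.05, "
      f"{int(diff['significant_10'].sum())} at adj-p <= 0.1")
# TE = footprint NTC minus RNA NTC per gene; the spike anchoring makes the
# mean TE difference between genotypes an estimate of the global factor.
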