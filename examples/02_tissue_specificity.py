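"""Tau tissue-specificity index on simple profiles and a planted matrix."""

from camlnc import SimulationConfig, average_by_tissue, call_specificity, hg_entropy, tau
from camlnc.synthetic_data import simulate_tissue_expression

for profile in [(5, 5, 5, 5), (0, 0, 30, 0), (1, 2, 4, 8)]:
    print(f"profile {profile}: tau = {tau(profile):.4f}, "
          f"Hg = {hg_entropy(profile):.3f} bits")
print("tau runs from 0 (uniform across tissues) to 1 (single tissue); "
      "low entropy likewise means high specificity.\n")

m, truth = simulate_tissue_expression(SimulationConfig(seed=1, noise_sd=0.0))
results = call_specificity(average_by_tissue(m))
specific = [r for r in results if r.is_tissue_specific]
print(f"{len(results)} transcripts scored after discarding FPKM<1 rows; "
      f"{len(specific)} are tissue-specific (tau > 0.8):")
for r in specific[:5]:
    print(f"  {r.transcript_id}: tau={r.tau:.3f} peak tissue={r.max_tissue}")
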