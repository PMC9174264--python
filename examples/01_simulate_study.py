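"""Generate a synthetic 8-group oral-microbiome study with known truth.

The design mirrors a polymicrobial periodontal-infection mouse experiment:
8 sequenced arms x 6 mice, ~120 bacterial+viral species, planted infection
effects and graded treatment recovery.  The printed truth rows show the
multiplicative effect each group applies to the focal disease virus.
"""

from periobiome import StudyDesign, generate_study

design = StudyDesign(seed=1)
counts, metadata, markers, truth = generate_study(design)

print(f"count table: {counts.data.shape[0]} taxa x {counts.data.shape[1]} samples")
print(f"mean library size: {counts.totals().mean():,.0f} reads")
print("\nplanted effect multipliers for the focal disease virus (vir_s001):")
print(truth.effect_multiplier.loc["vir_s001"].round(3).to_string())
print(
    "\n1.0 = control state; 4.0 = full infection effect; values in between\n"
    "reflect partial recovery under treatment (fold^(1-rho))."
)
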