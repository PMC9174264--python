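"""RPM-normalize a count table, filter rare taxa, and compare diversity.

Each sample is rescaled to one million reads (RPM); taxa averaging below
1 RPM are dropped; Shannon diversity (nats) and kingdom content are then
compared between the infection and control arms with pooled-variance
t-tests.
"""

from periobiome import (
    StudyDesign,
    compare_content,
    filter_low_abundance,
    generate_study,
    group_content_summary,
    normalize_rpm,
    shannon_by_sample,
)

counts, metadata, _, _ = generate_study(StudyDesign(seed=1))
abundance = filter_low_abundance(normalize_rpm(counts))
removed = abundance.provenance[-1]["removed_taxa"]
print(f"{len(removed)} taxa below 1 RPM removed; {len(abundance.taxon_ids)} retained")

div = shannon_by_sample(abundance, "bacteria").set_index("sample_id")
groups = metadata["group"]
h_ctrl = div.loc[groups[groups == "Control"].index, "H"]
h_inf = div.loc[groups[groups == "Infection"].index, "H"]
t = compare_content(h_inf, h_ctrl)
print(f"\nbacterial Shannon H: control {h_ctrl.mean():.3f}, infection {h_inf.mean():.3f}")
print(f"pooled t-test: t = {t.t:.3f}, df = {t.df}, p = {t.p:.4f}")

content = group_content_summary(abundance, "virus")
print("\nviral content (total RPM) with 95% CI per group:")
print(content.round(1).to_string(index=False))
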