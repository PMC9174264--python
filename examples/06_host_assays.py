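"""Host-assay statistics: qPCR load, ddCT expression, bone loss, defects.

Runs the non-sequencing readouts on a generated fixture bundle: pathogen
percentage of total 16S copies, 2^-ddCT relative expression of IL-6
against GAPDH, 28-site mean alveolar bone loss, and the chi-square test
on intrabony-defect proportions out of 72 tooth surfaces per group.
"""

import numpy as np

from periobiome import (
    StudyDesign,
    bone_loss_mean,
    ddct_fold_change,
    defect_chi_square,
    generate_assay_fixtures,
    pathogen_percentage,
    two_group_t,
)

fx = generate_assay_fixtures(StudyDesign(), seed=1)

q = fx.qpcr
pct = [
    pathogen_percentage(a, b)
    for a, b in zip(q.loc[q["group"] == "Infection", "P_gingivalis"],
                    q.loc[q["group"] == "Infection", "total_16s"])
]
print(f"P. gingivalis load, Infection group: {np.mean(pct):.2f}% of total 16S")

ct = fx.ct[fx.ct["gene"] == "IL-6"]
dd = ddct_fold_change(ct, "Control")
fold = dd.loc[dd["group"] == "Infection", "fold"]
print(f"IL-6 relative expression (2^-ddCT), Infection vs Control: "
      f"{fold.mean():.2f}-fold")

sites = [c for c in fx.bone_loss.columns if c.startswith("site_")]
bl = fx.bone_loss.assign(mean_mm=[bone_loss_mean(r) for r in fx.bone_loss[sites].to_numpy()])
ctrl = bl.loc[bl["group"] == "Control", "mean_mm"]
inf = bl.loc[bl["group"] == "Infection", "mean_mm"]
t = two_group_t(inf, ctrl)
print(f"bone loss: control {ctrl.mean():.3f} mm, infection {inf.mean():.3f} mm "
      f"(t = {t.t:.2f}, p = {t.p:.2e})")

d = fx.defects.set_index("group")
chi = defect_chi_square(int(d.loc['Infection', 'defects']), 72,
                        int(d.loc['Control', 'defects']), 72)
print(f"intrabony defects: infection {d.loc['Infection', 'defects']}/72 vs "
      f"control {d.loc['Control', 'defects']}/72, chi2 = {chi.chi2:.2f}, p = {chi.p:.2e}")
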