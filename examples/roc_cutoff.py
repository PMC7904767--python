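"""Derive an adequacy cut-off from case-level average cleansing scores.

Draws a cohort shaped like a 96-case validation set (88 adequate cases with
mean score 4.0, 8 inadequate with mean 2.9, SD 0.4), sweeps the ROC, and
selects the Youden-optimal threshold reported as the midpoint between the
straddling scores.
"""

from capclean import roc_curve, select_cutoff, simulate_score_cohort, group_summary

scores, labels = simulate_score_cohort(seed=0)
roc = select_cutoff(roc_curve(scores, labels), method="youden")

for name, sel in [("adequate", labels), ("inadequate", ~labels)]:
    g = group_summary(scores[sel], name)
    print(f"{name:10s} n={g.n:3d}  score {g.mean:.2f} +/- {g.sd:.2f}")
print(f"\nAUC {roc.auc:.3f}")
print(f"cutoff {roc.selected_cutoff:.2f}: sensitivity {roc.cutoff_sensitivity:.2f}, "
      f"specificity {roc.cutoff_specificity:.2f}")
# Scores at or above the cutoff predict clinically adequate preparation
# (overall grade A or B); below it, the examination is likely grade C.
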