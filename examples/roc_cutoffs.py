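"""Derive risk-category cut-offs from ROC curves on a synthetic cohort.

Hearing loss is dichotomized at 25, 40 and 60 dB HL; for each threshold the
OHLRA score's ROC curve is built and the operating point closest to the
ideal corner (sensitivity 1, specificity 1) gives the cut-off separating
two adjacent risk categories.
"""

import pandas as pd

from ohlra import DEFAULT_COEFFICIENTS, default_moments, derive_risk_cutoffs, generate_cohort

moments = default_moments()
cohort = generate_cohort(moments, n=10_000, seed=1, mode="continuous")
score = cohort[list(moments.names[:-1])].to_numpy() @ DEFAULT_COEFFICIENTS.as_array()
table = pd.DataFrame({"ohlra_score": score, "hearing_loss_dB": cohort["hearing_loss"]})

cuts = derive_risk_cutoffs(table)

print(f"{'threshold':>9s} {'cut-off':>8s} {'sens':>6s} {'spec':>6s} {'AUC':>6s} {'95% CI':>16s}")
for t, c, sn, sp, a, ci in zip(
    (25, 40, 60),
    (cuts.t_low_mod, cuts.t_mod_high, cuts.t_high_vhigh),
    cuts.sensitivity, cuts.specificity, cuts.auc, cuts.auc_ci,
):
    print(f"{t:>7d}dB {c:8.3f} {sn:6.3f} {sp:6.3f} {a:6.3f}   ({ci[0]:.3f}, {ci[1]:.3f})")

# The published cut-offs on the real cohort were 4.85 / 6.84 / 7.59 with
# AUCs 0.922 / 0.937 / 0.952.  A synthetic cohort built from the printed
# summary statistics lands near those values for the 25 and 60 dB
# thresholds; the 40 dB cut-off sits lower (~6.1), a known gap between the
# rounded printed moments and the raw data (see docs/methods.md).
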