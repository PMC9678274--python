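"""Subject-level bootstrap inference on criterion shifts.

Within-condition shift tests, a cross-condition comparison (mask vs
no-mask), the mixed ANOVA on accuracy and the per-pair shift counts —
the study's full inferential battery on one simulated panel.
"""

import facebias as fb

panel, _ = fb.attention_filter(fb.simulate_panel(fb.study1_config(seed=11)))

for cond in ("no_mask", "mask"):
    res = fb.shift_test(panel, cond, "c", B=5000, seed=3)
    print(
        f"delta_c [{cond}]: {res.estimate:+.3f} "
        f"(95% CI {res.ci_low:+.3f}..{res.ci_high:+.3f}, p = {res.p_two_sided:.3f})"
    )

cross = fb.cross_condition_shift_test(
    panel, panel, "c", B=5000, seed=3, condition_a="mask", condition_b="no_mask"
)
print(
    f"delta_c difference (mask - no_mask): {cross.estimate:+.3f} "
    f"(p = {cross.p_two_sided:.3f})"
)

anova = fb.mixed_anova_accuracy(panel, ("no_mask", "mask"))
eff = anova["between"]
print(
    f"mask effect on accuracy: F({eff.df_num}, {eff.df_den}) = {eff.F:.2f}, "
    f"p = {eff.p:.2g}"
)

for cond in ("no_mask", "mask"):
    k = fb.count_significant_pairs(panel, cond)
    print(f"face pairs with significant confidence shifts [{cond}]: {k} of 12")

print(
    "\nThe criterion shift is significant under masks, the mask-vs-no-mask"
    "\ndifference mirrors the doubling of bias, and masking lowers accuracy"
    "\nwhile the algorithm's label itself does not."
)
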