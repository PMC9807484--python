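"""Publication-bias testing: Begg, Egger and trim-and-fill.

A hand-built funnel whose effects grow with their variances (strict
concordance) triggers the exact small-sample Begg test; an asymmetric
funnel shows trim-and-fill imputing the suppressed counterpart and
re-pooling the corrected estimate.
"""

from mirameta.meta import EffectSize, pool_random_effects, tau2_reml
from mirameta.bias import begg_test, egger_test, trim_and_fill


def effects(ys, vs):
    return [EffectSize(y, v, False, f"sub{i}", f"study{i}")
            for i, (y, v) in enumerate(zip(ys, vs))]


# six substudies, effect strictly increasing with variance
concordant = effects([0.3, 0.9, 1.6, 2.5, 3.6, 5.0],
                     [0.05, 0.1, 0.25, 0.6, 1.2, 2.5])
tau, p, method = begg_test(concordant)
print(f"Begg ({method}): Kendall tau = {tau:.4f}, two-sided p = {p:.4f}")
print("  -> with k=6 and perfect concordance the exact p is 2/6! = 0.0028:")
print("     small-study effects this extreme arise by chance twice in 720 orderings\n")

intercept, z, p_e, _ = egger_test(concordant)
print(f"Egger: intercept = {intercept:.4f}, Z = {z:.4f}, p = {p_e:.4f}")
print("  -> a nonzero intercept means small (imprecise) substudies report"
      " systematically larger standardised effects\n")

# one small null substudy plus a cluster of large effects: right-side excess
skewed = effects([0.0, 3.0, 3.1, 3.2, 3.3], [1.0] * 5)
k0, filled, mu_adj, p_adj = trim_and_fill(skewed, side="right")
mu_naive, *_ = pool_random_effects(skewed, tau2_reml(skewed))
print(f"trim-and-fill: k0 = {k0} imputed study at y = {filled[-1].y:.2f}")
print(f"  pooled logOR {mu_naive:.3f} (naive) -> {mu_adj:.3f} (corrected), "
      f"p = {p_adj:.3g}")
print("  -> the corrected estimate moves toward the suppressed side;"
      " a biomarker must stay significant after this correction")
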