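"""Compare strain-energy samples between two conditions.

Emulates the comparison layer of a stiffness/treatment experiment:
per-frame strain energies pooled over fields of view are normalized to
the vehicle-control mean, tested with the Wilcoxon rank-sum test and
summarized as median fold changes with bootstrap confidence intervals.
"""

import numpy as np

from tfmkit.stats import compare_groups, fold_change_summary, normalize_to_control

rng = np.random.default_rng(0)
# synthetic strain-energy samples (nN/um), lognormal like pooled TFM metrics:
# treatment raises the median roughly 3-fold
samples = {
    "vehicle": rng.lognormal(mean=np.log(0.020), sigma=0.45, size=200),
    "treated": rng.lognormal(mean=np.log(0.060), sigma=0.45, size=200),
}

result = compare_groups(samples, "vehicle", "treated")
normalized = normalize_to_control(samples, "vehicle")
table = fold_change_summary(samples, "vehicle", seed=1)

print(f"vehicle: n={result.n[0]}, median {np.median(samples['vehicle']):.4f} nN/um")
print(f"treated: n={result.n[1]}, median {np.median(samples['treated']):.4f} nN/um")
print(f"rank-sum U = {result.statistic:.0f}, two-sided p = {result.p_value:.3g}")
print(f"normalized control mean: {normalized['vehicle'].mean():.3f} (by construction 1)")
print()
print(table.round(3).to_string(index=False))
print()
print("fold_change is the ratio of group medians to the baseline median; the")
print("bootstrap CI quantifies its sampling uncertainty.  A p-value << 0.01")
print("indicates the treated monolayers do significantly more work on the gel.")
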