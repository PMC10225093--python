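"""Remove multi-site scanner effects with parametric empirical-Bayes ComBat.

Edge-wise connectivity features carry additive and multiplicative site
effects.  `combat_adjust` shrinks per-site location/scale estimates with
empirical-Bayes priors while protecting biological covariates (group,
age, sex) through a design matrix.  `site_effect_metric` reports the
per-feature R-squared explained by site, before and after.
"""

import numpy as np
import pandas as pd

import cereconn as cc

rng = np.random.default_rng(11)
n, p = 240, 30

site = pd.Series(rng.integers(0, 3, n))
group = pd.Series(rng.choice(["HC", "MS"], n))
age = pd.Series(rng.uniform(20, 60, n))

values = pd.DataFrame(rng.standard_normal((n, p)),
                      columns=[f"edge{i}" for i in range(p)])
# additive + multiplicative site effects
for s in range(3):
    m = (site == s).to_numpy()
    values.loc[m] = values.loc[m] * (1.0 + 0.3 * s) + 0.8 * s
# a real group effect to protect
values.loc[(group == "MS").to_numpy(), "edge0"] += 0.7

ft = cc.FeatureTable(values, site, pd.DataFrame({"group": group, "age": age}))

pre = cc.site_effect_metric(ft)
out = cc.combat_adjust(ft)
post = cc.site_effect_metric(out)

print(f"site R^2 before: mean {pre.mean():.3f} (max {pre.max():.3f})")
print(f"site R^2 after:  mean {post.mean():.4f} (max {post.max():.4f})")

g = group.to_numpy()
eff_pre = values.loc[g == "MS", "edge0"].mean() - values.loc[g == "HC", "edge0"].mean()
eff_post = (out.values.loc[g == "MS", "edge0"].mean()
            - out.values.loc[g == "HC", "edge0"].mean())
print(f"group effect on edge0: before {eff_pre:.3f}, after {eff_post:.3f} "
      "(preserved)")
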