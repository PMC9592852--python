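"""The within-subject statistical suite on a small synthetic cell-means table.

Shows the RM ANOVA with Greenhouse–Geisser correction, Helmert
contrasts against the pooled error term, a paired t with Cohen's d and
noncentral-t CI, and the outlier-screened correlation.
"""

import numpy as np
import pandas as pd

from reachvigor import stats as st

rng = np.random.default_rng(42)

# 20 participants × 3 positions × 2 CS types of peak-velocity cell means
n = 20
subject_offset = rng.normal(0, 40, n)[:, None, None]
position_effect = np.array([220.0, 320.0, 400.0])[None, :, None]
cs_effect = np.array([8.0, 0.0])[None, None, :]  # CS+ faster by 8 cm/s
cells = subject_offset + position_effect + cs_effect + rng.normal(0, 15, (n, 3, 2))

rows = []
for s in range(n):
    for i, pos in enumerate(("low", "middle", "high")):
        for j, cs in enumerate(("CS+", "CS-")):
            rows.append({"participant": f"p{s:02d}", "position": pos,
                         "cs_type": cs, "v": cells[s, i, j]})
table = pd.DataFrame(rows)

anova = st.rm_anova(table, dv="v", subject="participant",
                    within=["position", "cs_type"])
print("RM ANOVA (position × stimulus type):")
for _, r in anova.iterrows():
    corr = " (GG-corrected)" if r.gg_applied else ""
    print(f"  {r.effect:20s} F({r.df1_corr:.2f},{r.df2_corr:.2f}) = {r.F:7.2f}, "
          f"p = {r.p:.4f}{corr}, ηp² = {r.partial_eta_sq:.2f} "
          f"[{r.eta_ci_lo:.2f}, {r.eta_ci_hi:.2f}]")

wide = table.pivot_table(index="participant", columns="position", values="v")
contrasts = st.helmert_contrasts(wide[["low", "middle", "high"]].to_numpy())
print("\nHelmert contrasts (pooled error, df = 2(n−1)):")
for c in contrasts:
    print(f"  {c.label:22s} t({c.df}) = {c.t:7.2f}, p = {c.p:.2g}")

plus = table[table.cs_type == "CS+"].groupby("participant")["v"].mean()
minus = table[table.cs_type == "CS-"].groupby("participant")["v"].mean()
t = st.paired_t(plus.to_numpy(), minus.to_numpy())
print(f"\npaired t (CS+ vs CS−): t({t.df}) = {t.t:.2f}, p = {t.p:.4f}, "
      f"d = {t.d:.2f} [{t.d_ci[0]:.2f}, {t.d_ci[1]:.2f}]")

x = rng.normal(size=30)
y = 0.6 * x + rng.normal(scale=0.5, size=30)
y[5] += 8.0  # gross outlier
res = st.robust_pearson(x, y)
print(f"\nrobust Pearson: r = {res.r:.2f} on {res.n_used} points "
      f"(removed {len(res.removed_points)} beyond 3 residual SDs)")
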