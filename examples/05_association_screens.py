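"""Univariate screens: what co-varies with MP abundance?

Spearman correlations of MP metrics against soil properties, climate and
population; OLS regression of abundance on population quantity; one-way
ANOVA with Duncan letters among regions; Welch t-tests between depth
layers.
"""

import mpcommunity as mpc

bundle = mpc.simulate_survey(seed=42)
summary = mpc.summarize_samples(bundle.particles, bundle.meta)
metrics = mpc.metric_table(bundle.particles, bundle.meta)

screen = mpc.spearman_screen(metrics, bundle.covariates)
strong = (screen.rho.abs() > 0.5) & (screen.p < 0.05)
print("Spearman pairs with |rho| > 0.5 and p < 0.05:")
for metric in strong.index:
    for cov in strong.columns:
        if strong.loc[metric, cov]:
            print(f"  {metric:>18} ~ {cov:<16} rho={screen.rho.loc[metric, cov]:+.2f}"
                  f"  p={screen.p.loc[metric, cov]:.3g}"
                  f"  q={screen.q.loc[metric, cov]:.3g}")

reg = mpc.simple_regression(bundle.covariates["population"],
                            summary["abundance"].loc[bundle.covariates.index])
print(f"\nabundance ~ population: R = {reg.r:.3f}, p = {reg.p_value:.3g}, "
      f"slope = {reg.slope:.2f} items/kg per 1e4 persons")

meta = bundle.meta.set_index("sample_id")
top = meta.index[meta["depth_layer"] == "0-20 cm"]
values = summary.loc[top, "abundance"].to_numpy()
regions = meta.loc[top, "region"].to_numpy()
f, p = mpc.one_way_anova(values, regions)
letters = mpc.duncan_letters(values, regions)
print(f"\ntopsoil abundance among regions: F = {f:.2f}, p = {p:.3g}")
print("Duncan letters (groups sharing a letter are not separated at alpha=0.05):")
for region in sorted(letters.means, key=letters.means.get, reverse=True):
    print(f"  {region}: {letters.means[region]:>8,.0f} items/kg  "
          f"{letters.letters[region]}")
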