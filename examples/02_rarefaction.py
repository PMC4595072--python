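"""Rarefy diversity components over sequencing depth.

Alpha and gamma diversity keep climbing with depth (new rare OTUs keep
appearing), while effective beta stabilizes after a few thousand reads —
the replicate standard deviation at depth 5000 is a fraction of that at
depth 100.
"""

from ednacompare import SyntheticConfig, rarefy_diversity, simulate_gradient_metacommunity

matrices, _, _ = simulate_gradient_metacommunity(SyntheticConfig(seed=2))
curve = rarefy_diversity(matrices["eDNA"], depths=[100, 500, 2000, 5000],
                         replicates=30, q=1.0, seed=2)
summary = curve.summary().pivot(index="depth", columns="component")
print(summary.round(3).to_string())
sd = curve.summary().query("component == 'beta'").set_index("depth")["std"]
print(f"\nbeta SD shrinks with depth: {sd[100]:.3f} at 100 reads -> "
      f"{sd[5000]:.3f} at 5000 reads")
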