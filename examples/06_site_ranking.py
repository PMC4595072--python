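"""Rank plots by conservation priority and compare rankings across methods.

The greedy rule removes, at each step, the plot whose removal leaves the
remaining set with the highest effective beta diversity — so the first
plots removed are compositionally redundant and the last survivors are
the most irreplaceable. Spearman's rho measures whether two survey
methods agree on the priority order.
"""

from ednacompare import (
    MarkerProfile,
    SyntheticConfig,
    greedy_beta_ranking,
    pool_to_plots,
    simulate_gradient_metacommunity,
    spearman_rank_correlation,
)

cfg = SyntheticConfig(profiles={
    "markerA": MarkerProfile(gradient_strength=1.0),
    "markerB": MarkerProfile(gradient_strength=0.9),
}, seed=6)
matrices, _, _ = simulate_gradient_metacommunity(cfg)
rankings = {m: greedy_beta_ranking(pool_to_plots(cm), q=1.0)
            for m, cm in matrices.items()}
for m, rk in rankings.items():
    order = " > ".join(p for p, _ in
                       sorted(rk.rank_of.items(), key=lambda kv: kv[1]))
    print(f"{m} priority (highest first): {order}")
rho, p = spearman_rank_correlation(rankings["markerA"], rankings["markerB"])
print(f"\nSpearman rank agreement: rho = {rho:.3f} (exact p = {p:.4f})")
print("(with only 10 plots this comparison has weak power: rankings react "
      "to sampling noise\n even when both markers share the same gradient)")
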