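"""Call bell/valley transient gene programs at the detected boundary.

Each gene is tested against both flanks (Mann-Whitney U, BH within each
comparison) and classified from the two log-fold changes; bell genes peak at
the gateway, valley genes dip there, ascending/descending genes are monotone.
"""

from gatewaykit.benchmarks import run_standard_pipeline

res = run_standard_pipeline(seed=1)
table, truth = res["table"], res["truth"]

print(table["class"].value_counts().to_string())
planted_bell = {f"gene_{i}" for i in truth.bell_genes}
planted_valley = {f"gene_{i}" for i in truth.valley_genes}

bell = table[table["class"] == "bell"].nlargest(10, "amplitude")
print("\ntop bell genes (amplitude = mean |LFC| vs the two flanks):")
for _, r in bell.iterrows():
    mark = "*" if r["gene"] in planted_bell else " "
    print(f" {mark} {r['gene']:<10} A={r['amplitude']:.2f} "
          f"lfc_src={r['lfc_source']:+.2f} lfc_tgt={r['lfc_target']:+.2f} "
          f"q=({r['q_source']:.1e}, {r['q_target']:.1e})")
print(f"\nplanted bell recovered: {res['bell_recovery']:.0%}, "
      f"valley recovered: {res['valley_recovery']:.0%}")
# '*' marks planted genes: the dual-flank test finds the genes that peak or
# dip specifically at the interface, which endpoint comparisons miss.
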