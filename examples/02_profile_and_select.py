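"""Profile one transcription pattern and select gene sub-sets.

Generates a planted dataset, sorts the deviation pattern's gene weights in
decreasing order, and selects genes three ways: the most stable (lowest
G_i0), the top contributors to the transformation pattern, and everything
outside a pair of value bounds.
"""

from surprisal import (
    decompose,
    generate_planted_dataset,
    log_transform,
    select_by_bounds,
    select_extremes,
    sort_pattern,
)

x, truth = generate_planted_dataset(m=2000, t=4, seed=42)
d = decompose(log_transform(x))

profile = sort_pattern(d, alpha=1)
print("deviation-pattern profile (sorted G_i1, decreasing):")
print("  top 3:   ", [(g, round(v, 3)) for g, v in profile.entries[:3]])
print("  bottom 3:", [(g, round(v, 3)) for g, v in profile.entries[-3:]])

stable = select_extremes(d, alpha=0, n=100, mode="most_negative")
contributing = select_extremes(d, alpha=1, n=100, mode="most_positive")
print(f"\n100 most stable genes (lowest G_i0): first 5 = {stable.gene_names[:5]}")
print(f"100 most contributing up-regulated genes: first 5 = {contributing.gene_names[:5]}")

planted_stable = {x.gene_names[i] for i in truth.stable_genes}
overlap = len(set(stable.gene_names) & planted_stable)
print(f"\nplanted-stable genes recovered by the selection: {overlap}/100")

high, low = select_by_bounds(profile, upper=0.05, lower=-0.05)
print(f"\nbound selection on pattern 1: {len(high)} genes above +0.05, "
      f"{len(low)} below -0.05 (the rest sit near zero and are not of interest)")
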