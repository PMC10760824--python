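"""Cross-entropy inference on a synthetic six-line panel.

Generates an mESC-like panel (six cell lines whose enhancer sits at
different genomic distances from the promoter, 2000 cells each), fits the
variable-alpha-and-mu model by minimizing the total cross entropy, and
reports recovery of the distance-law scale Theta per line.
"""

import numpy as np

from eptx import PanelRecipe, fit, generate_panel, total_objective

recipe = PanelRecipe(seed=7, n_cells=2000)
panel = generate_panel(recipe)
gen = recipe.params

print("panel:")
for line in panel:
    mean = float((np.arange(line.q.size) * line.q).sum())
    print(f"  {line.label}: distance {line.distance_kb:9.4f} kb -> d_G="
          f"{str(line.d_G):>4s} monomers, observed mean {mean:.2f} mRNA")

h_gen = total_objective(gen, panel, "var_alpha_mu")
res = fit(panel, "var_alpha_mu", n_starts=8, seed=1, context=gen)
print(f"\ntotal cross entropy: fitted {res.total_cross_entropy:.4f} "
      f"(generating parameters give {h_gen:.4f})")
for dg in (1, 3, 5, 8, 22):
    print(f"  Theta(d_G={dg:2d}): generating {gen.theta(dg):.3f}  "
          f"fitted {res.params.theta(dg):.3f}")
print("per-line KS distances:",
      {k: round(v, 4) for k, v in res.per_line_ks.items()})
print("-> the fit matches the generating cross entropy and recovers the "
      "distance-law scale; individual stiffnesses are only identified "
      "through Theta(d_G).")
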