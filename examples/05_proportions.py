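"""Subpopulation proportion statistics: Fisher exact tests and odds ratios.

The generator plants genotype/pathology effects on the amyloid-responsive
microglia (ARM) share; the cross-tabulated odds ratios recover them.
"""

import numpy as np

from armnet import (
    cross_tab,
    cross_tab_or,
    default_design,
    or_from_proportions,
    simulate_dataset,
)

design = default_design(seed=3)
cm, truth, meta = simulate_dataset(design)
mic = (truth.cell_type == "microglia") & ~truth.is_doublet
subtype = truth.microglia_subtype[mic]
samples = cm.sample_of_cell[mic]
at = meta.lookup("at_score")
apoe = meta.lookup("apoe")
trem2 = meta.lookup("trem2")


def condition(rule):
    """Per-cell condition label under a (sample -> label) rule."""
    return np.array([rule(s) for s in samples], dtype=object)


# pathology comparisons within TREM2 WT donors
by_at = condition(lambda s: at[s] if trem2[s] == "WT" else "excluded")
# TREM2 comparison within matched pathology (A+T+) and APOE (E3/E3) donors,
# since genotype effects are otherwise confounded with cohort composition
by_trem2 = condition(
    lambda s: trem2[s] if (at[s], apoe[s]) == ("A+T+", "E3/E3") else "excluded"
)

comparisons = [
    ("ARM, amyloid vs normal", by_at, "A+T-", "A-T-"),
    ("ARM, tau vs amyloid-only", by_at, "A+T+", "A+T-"),
    ("ARM, TREM2 R47H vs WT", by_trem2, "R47H", "WT"),
]
for name, cond, c1, c2 in comparisons:
    tab = cross_tab(subtype, cond, "arm", c1, c2)
    res = cross_tab_or(tab)
    p1, p2 = tab.a / (tab.a + tab.b), tab.c / (tab.c + tab.d)
    print(f"{name:26s} {100 * p1:5.1f}% vs {100 * p2:5.1f}%  "
          f"OR {res.or_point:6.3f}  95% CI [{res.ci_low:.3f}, {res.ci_high:.3f}]  "
          f"Fisher p {res.p_fisher:.2e}")

print("\nscale-free check from two proportions alone:",
      f"{or_from_proportions(0.775, 0.078):.2f}",
      "(OR implied by 77.5% vs 7.8%)")
# ORs far above 1 mean ARM is enriched in the first condition; far below 1,
# depleted — the planted pattern mirrors amyloid-driven ARM expansion and
# its suppression by tau pathology and the TREM2 risk variant.
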