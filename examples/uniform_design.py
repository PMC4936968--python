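"""Construct a uniform design by the good-lattice-point method.

Builds the U8(8^3) table for the three bioreactor factors (pH, agitation,
aeration), prints its level indices and physical settings, and compares its
centered L2 discrepancy (lower = more uniform) with the packaged campaign
layout taken from published design tables.
"""

from fermopt import centered_l2_discrepancy, make_uniform_design
from fermopt.datasets import table2_fixture, uniform_design_space

space = uniform_design_space()
design = make_uniform_design(8, 3).with_space(space)

print("Generated U8(8^3) — level indices and physical settings")
print(f"{'run':>3}  {'levels':>9}   pH   rpm   vvm")
for i in range(design.n_runs):
    lv = tuple(int(v) for v in design.level_matrix[i])
    s = design.settings(i)
    print(f"{i + 1:>3}  {str(lv):>9}  {s['pH']:.1f}  {s['agitation']:4.0f}  {s['aeration']:.1f}")

fixture, _ = table2_fixture()
gen_disc = centered_l2_discrepancy(design.level_matrix, 8)
fix_disc = centered_l2_discrepancy(fixture.level_matrix, 8)
print(f"\ncentered L2 discrepancy: generated {gen_disc:.4f}, packaged campaign {fix_disc:.4f}")
print("(both spread 8 runs over an 8x8x8 grid; each column is a permutation of 1..8)")
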