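"""Replay the rotating-simplex campaign on the packaged five-run record.

Starting from four trial fermentations, the worst run (lowest xylitol
concentration) is reflected through the centroid of the other three to
propose the next experiment; the loop stops when the new run fails to beat
the simplex it came from.
"""

from fermopt import propose_simplex_point, select_worst, simplex_should_stop
from fermopt.datasets import table1_fixture

region, runs = table1_fixture()

print("Initial simplex (4 runs):")
for r in runs[:4]:
    print(f"  run {r.run_id}: pH {r.settings['pH']:.1f}, {r.settings['agitation']:.0f} rpm, "
          f"{r.settings['aeration']:.1f} vvm -> {r.response_value('concentration'):.1f} g/L xylitol")

worst = select_worst(runs[:4], "concentration")
print(f"\nworst run: {runs[worst].run_id} "
      f"({runs[worst].response_value('concentration'):.1f} g/L)")

proposal = propose_simplex_point(runs[:4], worst, region)
print("reflected proposal: "
      f"pH {proposal.settings['pH']:.1f}, {proposal.settings['agitation']:.0f} rpm, "
      f"{proposal.settings['aeration']:.1f} vvm"
      + ("  [outside the initial region — not clipped]" if proposal.out_of_bounds else ""))

print(f"\nexecuted as run 5 -> {runs[4].response_value('concentration'):.1f} g/L")
stop = simplex_should_stop(runs, "concentration")
best = max(runs[:4], key=lambda r: r.response_value("concentration"))
print(f"stop: {stop} (no improvement over run {best.run_id}'s "
      f"{best.response_value('concentration'):.1f} g/L; "
      f"run {best.run_id} is taken as the simplex optimum)")
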