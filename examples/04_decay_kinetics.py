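"""Fit decay kinetics to the bundled longitudinal density tables.

Fits the whole-retina density time courses of the two optic-neuropathy
models (pONT: partial optic nerve transection; OHT: ocular hypertension)
to the one-phase decay y = (Y0-Plateau)*exp(-K*X) + Plateau, and to the
two-phase model with rates fixed at the primary (t1/2 = 1.7 d) and
secondary (t1/2 = 16.3 d) degeneration half-lives, which estimates PF —
the percentage of the loss attributable to primary degeneration.
"""

from rgcmosaic import fit_one_phase, fit_two_phase, percent_loss, round_half_away
from rgcmosaic.datasets import CONTROL_DENSITY_PER_MM2, density_series, load_density_table

table = load_density_table()
print("percentage loss vs naive controls (computed -> published):")
for _, row in table.iterrows():
    computed = round_half_away(percent_loss(row["density"], CONTROL_DENSITY_PER_MM2))
    print(f"  {row['model']:18s} day {row['day']:3.0f}: "
          f"{computed:3d}% -> {row['printed_loss_pct']:3d}%")

for model in ("pONT", "OHT"):
    series = density_series(model)
    one = fit_one_phase(series)
    two = fit_two_phase(series)
    print(f"\n{model} whole-retina kinetics:")
    print(f"  one-phase: Y0 {one.y0:7.1f}, plateau {one.plateau:6.1f}, "
          f"t1/2 {one.half_life_days:5.2f} d, loss {one.percent_loss:4.1f}%")
    print(f"  two-phase: PF {two.pf_percent:5.1f}% primary degeneration "
          f"(spans SF {two.span_fast:6.1f} + SS {two.span_slow:6.1f} "
          f"= {two.y0 - two.plateau:6.1f})")
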