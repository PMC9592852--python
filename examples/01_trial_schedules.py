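"""Generate the three phases' trial schedules and check their structure.

The reaching phases cross 2 stimulus types (CS+, CS−) with 3 target
positions (low, middle, high), 20 trials per cell, fully shuffled.  The
Pavlovian learning phase uses 9 trials per cell with 7 of 9 CS+ trials
reinforced per position, a fixed lead-in (one CS− and one reinforced
CS+ per position), and never more than two consecutive stimuli of the
same type thereafter.
"""

from reachvigor import design as dz

geometry = dz.ScreenGeometry(diagonal_inches=43.0, resolution_x=1920, resolution_y=1080)
print(f"pixel pitch: {geometry.px_to_cm:.4f} cm/px "
      f"(a 64 px stimulus is {64 * geometry.px_to_cm:.2f} cm wide)")

baseline = dz.generate_reaching_schedule(n_per_cell=20, seed=7, phase="baseline")
print(f"\nbaseline: {len(baseline)} trials, "
      f"{len(baseline.cell_counts())} condition cells of "
      f"{baseline.cell_counts()[('CS+', 'low')]} trials each")

pav = dz.generate_pavlovian_schedule(n_per_cell=9, reinforced_per_cell=7, seed=7)
print(f"learning: {len(pav)} trials, "
      f"reinforcement rate {100 * pav.reinforcement_rate():.1f}% "
      f"(21 of 27 CS+ presentations carry the shock)")

print("\nfirst six trials (lead-in, one per cell, CS+ always reinforced):")
for t in pav.trials[:6]:
    tag = "US" if t.reinforced else "  "
    print(f"  {t.cs_type:3s} {t.position:6s} {tag}")

runs = dz._max_run_length([t.cs_type for t in pav.trials[6:]])
print(f"\nlongest same-type run after the lead-in: {runs} (cap is 2)")
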