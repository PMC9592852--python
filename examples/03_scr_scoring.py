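"""Simulate a learning-phase skin-conductance trace and score it trough-to-peak.

The scorer decimates the signal to 200 Hz and accepts a deflection only
if its trough starts 0.5–4.5 s after CS onset, rises for at most 5 s,
and exceeds 0.02 μS; anything else scores zero with a reason code.
"""

from reachvigor import design as dz
from reachvigor import scr_scoring as scr
from reachvigor import synth_scr as ss

schedule = dz.generate_pavlovian_schedule(9, 7, seed=5)
params = ss.ScrParams()  # 1250 Hz, CS+ 0.60 μS vs CS− 0.26 μS mean amplitude

trace = ss.simulate_scr_trace(schedule, params, seed=5)
print(f"simulated {trace.t_s[-1]:.0f} s of conductance at "
      f"{trace.sample_rate_hz:.0f} Hz ({len(trace.events)} CS events)")

pre = scr.preprocess(trace, target_rate_hz=200.0)
scores = scr.score_events(pre, schedule=schedule)

print("\nper-trial scores (first 8):")
for _, row in scores.head(8).iterrows():
    print(f"  trial {row.trial:2d} {row.cs_type:3s}: "
          f"{row.amplitude_uS:5.3f} μS  ({row.zero_reason})")

summary = scr.participant_scr_summary(scores)
row = summary.iloc[0]
print(f"\nmean SCR  CS+: {row.scr_cs_plus_uS:.2f} μS   CS−: {row.scr_cs_minus_uS:.2f} μS")
print(f"differential (CS+ − CS−): {row.scr_differential_uS:.2f} μS")
print("a positive differential is the signature of successful threat learning")
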