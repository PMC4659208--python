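"""Reproduce the published percentage-change table from published totals.

The packaged fixture holds the total flow rates printed by the original
3D imaging study for every (configuration, stenosis degree) cell.  The
percentage-change operation with the (complete, 0 %) reference recovers
the study's derived table exactly at two-decimal rounding — a check of
the reporting arithmetic that is independent of any solver.
"""
from cowflow import percentage_change_table, published_total_flows

totals = published_total_flows()
print("published total flows (ml/s):")
print(totals.to_string())

change = percentage_change_table(totals)
print("\nrecomputed percentage change (%):")
print(change.to_string())

print("\ne.g. occlusion of the RICA costs", -change.at[100.0, "COMPLETE"],
      "% of total flow in the complete circle, and",
      -change.at[100.0, "LA1_ABSENT"], "% when the left A1 is absent.")
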