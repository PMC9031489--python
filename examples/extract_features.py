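"""Extract the 26-feature HRV vector for the epochs of one patient.

Shows the per-epoch battery at 180 s: time-domain statistics, neonatal
frequency bands, and the entropy family, with seizure epochs labeled under
the any-sample rule.
"""

import pandas as pd

from neohrv import CohortConfig, build_feature_table, generate_cohort

cfg = CohortConfig(n_controls=0, n_pathological=1, record_length_s=1800.0, seed=5)
patients = generate_cohort(cfg)
table = build_feature_table(patients, epoch_length_s=180.0, rule="any_sample")

pd.set_option("display.width", 120)
cols = ["epoch_index", "label", "HR", "SDNN", "TRI", "LFHFratio", "ApEn", "MSE_1", "MDE_1"]
print(table[cols].round(3).to_string(index=False))
seiz = table[table.label == "seizure"]
non = table[table.label == "non_seizure"]
print(f"\nmean HR  seizure vs non-seizure epochs: {seiz.HR.mean():.1f} vs {non.HR.mean():.1f} bpm")
print(f"mean SDNN seizure vs non-seizure epochs: {seiz.SDNN.mean():.2f} vs {non.SDNN.mean():.2f} ms")
# During events the generator raises heart rate and suppresses variability.
# Seizure epochs therefore show clearly elevated HR; epoch-level dispersion
# measures (SDNN, TRI) can nevertheless rise in epochs that straddle an
# onset/offset, because the step change in mean RR itself adds variance —
# purely within-event RR segments do have reduced variability.
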