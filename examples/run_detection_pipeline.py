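"""Run the full detection pipeline on a small synthetic cohort.

Simulates 4 controls + 4 seizure patients (20 min each), extracts 180 s
epoch features, trains a cost-weighted Gaussian maximum-margin classifier
on the top-2 mRMR features under leave-one-subject-out validation, and
prints the epoch/event metric summary.
"""

import tempfile

from neohrv import CohortConfig, ModelConfig, PipelineConfig, report, run_pipeline

cfg = PipelineConfig(
    cohort=CohortConfig(n_controls=4, n_pathological=4, record_length_s=1200.0),
    epoch_length_s=180.0,
    rule="any_sample",
    configs=[ModelConfig(kernel="gaussian", kernel_scale=1.0, c2=5.0)],
    n_features_menu=(2,),
    seed=11,
)
with tempfile.TemporaryDirectory() as out:
    metrics = run_pipeline(cfg, out)
    print(f"mean pathological AUC: {metrics['mean_pathological_auc']:.3f}")
    print(f"concatenated AUC:      {metrics['concatenated_auc']:.3f}")
    print()
    print(report(out))
# AUC near 1 reflects the strong planted ictal effect; the event rows show
# GDR (events caught), FDH (false events per hour) and the detection delay
# implied by 180 s epochs.
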