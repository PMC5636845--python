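"""Extract the 46 maturational features and show their age trends.

Each accepted epoch is summarised by 23 features on the full epoch and
23 on its low-SAT% segment: envelope and range-EEG percentiles, band
powers, SAT timing statistics and interhemispheric synchrony.
"""

import numpy as np
import pandas as pd

from neonatal_ema import CohortConfig, PipelineConfig, cohort_feature_table
from neonatal_ema.synthetic import generate_recording

config = CohortConfig(duration_s=600.0)
recs = []
for k, pma in enumerate((170, 195, 220, 245, 264)):
    rec, _ = generate_recording(f"i{k}", f"i{k}_r0", pma, config,
                                np.random.default_rng(30 + k))
    recs.append(rec)

features = cohort_feature_table(recs, PipelineConfig(epoch_len_s=600.0))
cols = ["pma_days", "sats_per_hour_full", "isi_p95_full",
        "reeg_p95_full", "rel_beta_full"]
with pd.option_context("display.float_format", "{:.2f}".format):
    print(features[cols].to_string(index=False))
print()
print("With age: bursts per hour rise, the 95th-percentile inter-SAT")
print("interval shrinks, amplitudes (rEEG) grow and beta weight increases -")
print("the monotone trends the regression maps to a brain age.")
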