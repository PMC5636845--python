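"""Compare reduced electrode montages against the full 8-channel set.

Streamlined NICU monitoring often records only 2 or 4 channels; the
paired Wilcoxon signed-rank test on per-recording squared errors asks
whether the reduction costs accuracy.
"""

from neonatal_ema import CohortConfig, PipelineConfig, cohort_feature_table, generate_cohort
from neonatal_ema.ema_model import ModelConfig, run_loio
from neonatal_ema.evaluation import compare_montages
from neonatal_ema.pipeline import MONTAGE_VARIANTS

cohort = CohortConfig(n_infants=8, duration_s=600.0, seed=21)
_, recordings = generate_cohort(cohort)
recs = [r for r, _ in recordings]
pipe = PipelineConfig(epoch_len_s=600.0)

tables = {}
for name in ("8ch", "4ch Fp-T, T-O", "2ch Fp-T"):
    features = cohort_feature_table(recs, pipe, channels=MONTAGE_VARIANTS[name])
    ema, _ = run_loio(features, ModelConfig(seed=3, feature_selection=False))
    tables[name] = ema

result = compare_montages(tables, reference="8ch")
print(result.to_string(index=False,
                       float_format=lambda v: f"{v:.3f}"))
print()
print("p_value tests each variant's squared errors against the 8-channel")
print("reference (paired, two-sided); comparable MSEs mean the reduced")
print("montage preserves the maturational information.")
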