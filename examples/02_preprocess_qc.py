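"""Standardise two volumes with different raw intensity scales.

Volumes from different scanners arrive with heterogeneous bit depths; after
scaling, quantile clipping and rescaling, every volume occupies exactly
[-1, 1], ready for a tanh-output generator.
"""

from bmelseg.phantom import PhantomConfig, generate_study
from bmelseg.preprocess import histogram_report, preprocess_study

a = generate_study(PhantomConfig(), seed=100)
b = generate_study(PhantomConfig(), seed=101)

raw = histogram_report({"study_a": a.target, "study_b": b.target})
print("raw target-volume ranges (per-volume intensity scales differ):")
print(raw[["volume_id", "min", "max"]].to_string(index=False))

pp = histogram_report({"study_a": preprocess_study(a).target,
                       "study_b": preprocess_study(b).target})
print("\nafter preprocessing (identical [-1, 1] ranges):")
print(pp[["volume_id", "min", "max"]].to_string(index=False))
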