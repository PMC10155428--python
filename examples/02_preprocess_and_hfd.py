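"""Preprocess a session and measure envelope complexity.

The signal chain: 10-300 Hz Butterworth bandpass (zero phase), median
filtering of the stimulation-artifact channels, 100 ms RMS envelopes, trial
segmentation, time normalization to 7000 points and min-max amplitude
normalization.  The Higuchi fractal dimension of each trial envelope
quantifies its complexity: smooth volitional bursts sit near 1, noise-like
activity near 2.
"""

import synergykit as sk
from synergykit.hfd import HFDParams, complexity_table

gen = sk.GeneratorConfig(n_synergies=3, noise_sd=0.05, seed=7)
record, _ = sk.synthesize_session(gen, group="SCI", participant_id="S2")
prep = sk.preprocess_session(record, sk.PipelineConfig())

print(f"time-normalized trials: {len(prep.trials_raw)} "
      f"(each {next(iter(prep.trials_raw.values())).shape})")
print(f"ensemble envelopes: {len(prep.ensembles)}")

table = complexity_table(prep.trials_raw, record.channel_names,
                         HFDParams(k_max=64), participant_id="S2")
summary = table.groupby("condition").hfd.mean()
print("\nmean fractal dimension by condition:")
print(summary.round(3).to_string())
# Both conditions sit near 1 because the 7000-point time normalization
# interpolates (hence smooths) the envelopes; what matters is the contrast:
# the noise-only no_stim envelopes are consistently rougher than the smooth
# planted bursts of the stim condition.
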