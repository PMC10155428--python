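"""Project movement envelopes onto lumbosacral spinal segments.

Each segment's estimated alpha-motor-neuron activity is the myotomal-chart
weighted average of the muscle envelopes, S[j, t] = sum_i k_ij E[i, t] / n_j,
over segments L1..S1.
"""

import numpy as np

import synergykit as sk
from synergykit.spinalmap import load_chart, map_to_segments

gen = sk.GeneratorConfig(n_synergies=3, noise_sd=0.03, seed=3)
record, _ = sk.synthesize_session(gen, group="control", participant_id="C1")
prep = sk.preprocess_session(record, sk.PipelineConfig())
chart = load_chart()                       # built-in Sharrard-derived default

print("chart muscles per segment:", dict(zip(chart.weights.columns, chart.n_j)))
env = prep.ensembles[0]
sm = map_to_segments(env, chart)
print(f"\nmovement {sm.movement_id} ({sm.condition}): "
      f"activity {sm.activity.shape[0]} segments x {sm.activity.shape[1]} points")
peak = np.array(sm.segments)[sm.activity.max(axis=1).argmax()]
print("segment activity maxima:",
      dict(zip(sm.segments, np.round(sm.activity.max(axis=1), 3))))
print(f"most active segment: {peak}")
# The per-segment maxima show where along the rostro-caudal axis the
# movement's estimated motor-neuron drive concentrates.
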