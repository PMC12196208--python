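"""Train the multimodal fusion classifier on a small synthetic split.

Builds an AD-vs-control cohort, trains the three per-modality extractors
and the fusion CNN on six subjects per class, and scores the two held-out
subjects per class at frame and subject level. Takes a few minutes on one
CPU.
"""

import numpy as np

from eegfusion import evaluation
from eegfusion.pipeline import (FusionPipeline, build_frame_dataset,
                                small_pipeline_config)
from eegfusion.synthetic import SyntheticSpec, generate_cohort

spec = SyntheticSpec(n_subjects_per_class=8, classes=("A", "C"),
                     duration_s=30.0, effect_size=1.0, seed=1)
data = build_frame_dataset(generate_cohort(spec), ("A", "C"),
                           frames_per_subject=10)
print(f"dataset: {len(data)} frames from 16 subjects")

sids = np.unique(data.subject_ids)
test_ids = [s for s in sids if s.endswith(("006", "007"))]
test_mask = np.isin(data.subject_ids, test_ids)

pipe = FusionPipeline(small_pipeline_config(seed=7), n_classes=2)
pipe.fit(data.subset(~test_mask))

test = data.subset(test_mask)
pred, probs = pipe.predict(test)
print(f"held-out frame accuracy: {(pred == test.y).mean():.2f}")

for sid in test_ids:
    mask = test.subject_ids == sid
    voted = evaluation.subject_vote(pred[mask].tolist(), positive_class=0,
                                    frame_probabilities=probs[mask])
    truth = int(test.y[mask][0])
    print(f"{sid}: true={'AC'[truth]}  voted={'AC'[voted]}  "
          f"({np.sum(pred[mask] == truth)}/{mask.sum()} frames correct)")
print("a correct pipeline recovers the planted slowing effect on subjects "
      "it never saw during training")

triples = pipe.feature_triples(test)
rep = evaluation.correlation_matrix(
    np.stack([t.f_spec for t in triples]),
    np.stack([t.f_scal for t in triples]),
    np.stack([t.f_hht for t in triples]))
print("\nfeature-similarity matrix (spectrogram/scalogram/hilbert):")
print(np.round(rep.R, 3))
print("off-diagonal magnitudes well below 1 indicate the three "
      "representations contribute complementary information")
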