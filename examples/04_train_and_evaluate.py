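"""End-to-end synthetic recovery: generate, preprocess, train, evaluate.

Generates 500 N/AF episodes (R-R CV 0.03 vs 0.25), trains the reduced
two-block classifier for 5 epochs (batch 16, learning rate 1e-4), and
evaluates one held-out inter-patient fold — no subject appears in both
training and validation.  Prints the five evaluation metrics; both
sensitivity (AF recall) and specificity (N recall) should exceed 0.95.

Takes a minute or two on one CPU.
"""

from afibnet import ModelConfig, TrainConfig, run_protocol
from afibnet.experiments import build_episode_set

values, labels, subjects = build_episode_set(seed=1000)
print(f"{len(values)} episodes from {len(set(subjects))} subjects")

result = run_protocol(
    values, labels, subjects,
    ModelConfig.scaled(n_classes=2),
    TrainConfig(epochs=5, seed=1),
    split_mode="inter_patient",
    folds=[0],
)
summary = result.summaries[0]
for name, value in summary.items():
    print(f"{name:>12}: {100 * value:6.2f}%")
print("\nSensitivity = AF detection rate, specificity = sinus-rhythm "
      "rejection rate, on subjects the model never saw in training.")
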