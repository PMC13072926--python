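"""Train the CNN state classifier under grouped five-fold cross-validation.

Frames of an MD trajectory are strongly autocorrelated, so random
train/test splits leak information.  Instead each trajectory is cut into
10 contiguous chronological groups, each group into 5 contiguous
sub-blocks, and fold k validates on sub-block k of every group -- the
validation frames always interleave chronologically with training frames
from the *same* trajectory, but are never their immediate duplicates.

Run:  python examples/03_classify.py
"""

import numpy as np

import pixelmd as px

spec = px.SyntheticSpec(
    n_residues=60, n_trajectories_per_state=1, n_frames=150,
    mean_shift=3.0, fluctuation_sigma=0.5, seed=7,
)
data = px.simulate_dataset(spec)
ensembles = [e for s in spec.state_labels for e in data[s]]
ref = ensembles[0].coords[0]
aligned = [px.align_ensemble(e, ref) for e in ensembles]
dataset = px.encode_ensemble(aligned)

counts = [e.n_frames for e in ensembles]
folds = px.make_fold_assignment(counts)
print(f"{dataset.n_samples} frames, fold validation sizes: "
      f"{[len(folds.val_indices(f)) for f in range(1, 6)]}")

cfg = px.ClassifierConfig(epochs=15, seed=7)
cv = px.cross_validate(dataset, folds, cfg, log=print)
print()
print(cv.to_frame().to_string(index=False))
print(f"\nmean CV accuracy: {cv.mean_accuracy:.4f}")

# the retained fold model predicts calibrated probabilities
clf = cv.models[int(np.argmax(cv.fold_accuracies))]
probs = clf.predict_proba(dataset.images[:3])
for i, p in enumerate(probs):
    print(f"frame {i}: " + ", ".join(
        f"P({c})={v:.3f}" for c, v in zip(clf.classes, p)))
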