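# deepida

Joint association and classification for multi-view data, with
bootstrap/permutation feature ranking.

Modern molecular studies measure several data *views* — proteomics,
metabolomics, transcriptomics — on the same samples, each sample carrying
a class label (disease group, severity, treatment arm). Two questions
usually arrive together: *how do the views co-vary*, and *what separates
the classes*? `deepida` answers them in one step. Per-view feed-forward
networks f^d map each view to a low-dimensional representation
H^d = f^d(X^d); orthonormal projections Gamma_d are then chosen to
maximize

    rho/D · Σ_d tr(Γ_d' M_d Γ_d)
    + 2(1−rho)/(D(D−1)) · Σ_{d<j} ‖Γ_d' N_dj Γ_j‖²_F

where M_d = S_t^{−1/2} S_b S_t^{−1/2} is the whitened between-class
scatter of H^d (class separation) and N_dj = S_t^{d,−1/2} S_dj S_t^{j,−1/2}
the whitened cross-view scatter (association). The projections solve an
alternating eigensystem; the networks are trained by gradient descent on
the negated objective, with an analytic (envelope) gradient through the
scatter matrices — no autodiff framework involved. New samples are
classified by nearest centroid on the pooled representations, and
features are ranked by how often permuting them degrades out-of-bag
accuracy across an ensemble of bootstrap-trained models.

The objective is bounded (eigenvalues of M_d lie in [0,1] for balanced
classes; associations are squared correlations), so training cannot
diverge — a practical advantage over within-scatter-constrained
alternatives.

## Worked example

```python
import numpy as np
import deepida as di

# two-view, three-class Gaussian design with 20 planted signal
# features per view (block-correlated, cross-view association 0.4/0.2)
train, signals = di.simulate_linear(1, seed=2, n_k=(180, 180, 180))
test, _ = di.simulate_linear(1, seed=3, n_k=(180, 180, 180))

spec = di.NetworkSpec.uniform(2, hidden=(128, 64), output=5)
cfg = di.TrainConfig(epochs=30, lr=5e-3, batch_size=108, init_scale=0.1)

ranking = di.rank_features(train, spec, cfg, M=20, seed=7)
print([int(i) for i in ranking.top(0, r=5)])
# [2, 12, 13, 16, 19]    <- 5 of the 20 planted view-1 signals

selected, model, acc = di.select_and_retrain(
    train, test, ranking, spec, cfg, top=20)
print(f"test error {100 * (1 - acc):.1f}%")
# test error 29.8%
```

The ranking's `proportions` are occurrence proportions n_k/N_k: the
fraction of bootstrap pairs in which permuting feature k reduced
out-of-bag accuracy, among pairs that sampled k. Retraining on the
top-20 features per view recovers a ~22–30% three-class test error on
this design (chance is 66.7%), versus ~45% when training on all 1000
features per view — feature selection is what makes the deep model
competitive here.

A command-line interface mirrors the library:

```sh
deepida simulate --scenario linear-1 --seed 7 --outdir sim/
deepida rank --view sim/view1.tsv --view sim/view2.tsv \
        --labels sim/labels.tsv -M 20 --outdir rank/
```

Views are TSV/CSV matrices (samples × features, header row + id column);
outputs are TSV tables and JSON metrics with the seed and config hash
recorded.

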