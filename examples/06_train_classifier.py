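"""Train a regularized linear-discriminant classifier on a labelled matrix.

The published multi-peptide panels are applied, not refit; training here
exercises the same scoring machinery on synthetic cohorts, e.g. to check
that planted marker directions are recoverable.
"""

import numpy as np
from sklearn.metrics import roc_auc_score

from cemspipe import SyntheticConfig, score_matrix, simulate_study, train_model
from cemspipe.matching import PeptideMatrix
import pandas as pd

cfg = SyntheticConfig(n_patients=200, seed=12)
study = simulate_study(cfg)

# use the true abundances as a clean matrix; label = severe vs mild disease
mat = PeptideMatrix(
    study.truth.abundance,
    pd.DataFrame(
        {"mass_da": study.panel_meta["mass_da"],
         "time_min": study.panel_meta["time_min"], "support": 200},
        index=study.truth.abundance.index,
    ),
)
labels = (study.truth.severity > study.truth.severity.median()).astype(int)

train_ids = list(labels.index[:100])
test_ids = list(labels.index[100:])
# full shrinkage = diagonal covariance: each peptide is weighted by its
# marginal class separation, so weight signs are easy to read off
model = train_model(
    PeptideMatrix(mat.intensities[train_ids], mat.peptides), labels.loc[train_ids],
    regularization=1.0,
)
scores = score_matrix(PeptideMatrix(mat.intensities[test_ids], mat.peptides), model)
auc = roc_auc_score(labels.loc[test_ids], scores["score"])
print(f"held-out AUROC: {auc:.3f}  (chance = 0.5)")

w = model.panel.set_index("peptide_id")["weight"]
dirs = study.marker_directions["direction"]
agree = (np.sign(w.loc[dirs.index]) == dirs).mean()
print(f"weight-sign agreement with planted marker directions: {agree:.0%}")
# High AUROC and sign agreement mean the discriminant found the planted
# serum-protein-up / collagen-down structure, not noise.
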