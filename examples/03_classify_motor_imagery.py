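"""The full cross-validated motor-imagery pipeline on synthetic EEG.

Generates a 3-subject, two-class trial dataset in which the latent sources
of class 1 peak near 10 Hz (mu band) and those of class 2 near 20 Hz (beta
band), then runs class-wise IVA + AR feature extraction + max-margin
classification with k-fold cross-validation and per-fold initialisation
search.  Prints per-subject accuracy (mean +/- sd over folds).
"""

import numpy as np

from ivamotor import PipelineConfig, generate_two_class_dataset, run_cv_pipeline

ds, truth = generate_two_class_dataset(K=3, M=4, n_trials_per_class=24, T=200, seed=8)
cfg = PipelineConfig(n_init=4, kf=3, iva_max_iter=24, iva_tol=1e-5, seed=1)

report = run_cv_pipeline(ds, cfg)
for sid, acc, sd in zip(report.subject_ids, report.mean_accuracy, report.sd_accuracy):
    print(f"subject {sid}: accuracy {acc:.3f} +/- {sd:.3f}")
print(f"selected initialisation per fold: {report.selected_inits.tolist()}")
print("\n(accuracy near 1.0 reflects the planted 10 vs 20 Hz spectral "
      "separation; chance level is 0.5)")
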