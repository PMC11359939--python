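"""Cross-subject SCV correlation tables and initialisation-accuracy KDE.

Runs the pipeline while collecting, per class and fold, the cross-subject
correlation matrix of every IVA component on the test trials, then prints
each subject's strongest fold-averaged correlations (the subject-clustering
signal) and summarises how validation accuracy varied over random IVA
initialisations.
"""

import numpy as np

from ivamotor import (
    PipelineConfig,
    generate_two_class_dataset,
    kde_accuracy,
    run_cv_pipeline,
    top_correlations,
)

ds, truth = generate_two_class_dataset(K=3, M=4, n_trials_per_class=24, T=200, seed=8)
cfg = PipelineConfig(n_init=6, kf=3, iva_max_iter=24, iva_tol=1e-5, seed=1)
report = run_cv_pipeline(ds, cfg, collect_scv=True)

print("top cross-subject correlations (right-hand class):")
records = top_correlations(report.scv_matrices[1], class_label=1, top_n=3)
for subject, recs in records.items():
    sid = report.subject_ids[subject]
    for r in recs:
        partner = report.subject_ids[r.subject_pair[1]]
        print(f"  {sid} with {partner}: component {r.component_index}, "
              f"r = {r.value:+.3f} (mean of {r.n_folds} folds)")

acc = report.init_accuracies[0].mean(axis=1)  # fold 0, mean across subjects
print(f"\nvalidation accuracy over {len(acc)} initialisations "
      f"(fold 0): min {acc.min():.3f}, max {acc.max():.3f}")
if acc.std() > 0:
    curve = kde_accuracy(acc)
    mode = curve.grid[np.argmax(curve.density)]
    print(f"KDE mode at accuracy {mode:.3f} (bandwidth {curve.bandwidth:.3f}); "
          f"a long right tail would signal rare, unusually good initialisations")
else:
    print("all initialisations reached identical accuracy; KDE not informative")
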