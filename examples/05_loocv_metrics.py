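"""Leave-one-out cross-validation with aggregated confidences.

Each peptide is scored by a model trained on all the others; the n
held-out confidences form one ROC curve (the "general" AUC) and, at the
0.5 decision threshold, one confusion matrix from which sensitivity,
specificity, precision, accuracy and F1 follow.
"""

from cyspresso import evaluation, models, pipeline, synthetic

ds = synthetic.generate(
    synthetic.SyntheticConfig(n_samples=100, effect_size=3.0, seed=9)
)
X = pipeline.pooled_features(ds.records, ds.representations)
trainer = pipeline.head_trainer(
    models.ClassifierSpec("random_forest", n_trees=100, seed=0), X, ds.labels
)
report = evaluation.loocv(trainer, ds.labels)

print("LOOCV on 100 synthetic peptides (100-tree forest, pooled features)")
for key, value in report.to_report().items():
    print(f"  {key} = {value}")
# tp/fp/tn/fn are counts at threshold 0.5; the metrics are their usual
# closed forms, reported to 3 decimals.
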