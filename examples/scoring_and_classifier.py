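"""Median scoring of feature genes and the neural-network classifier.

Feature-gene expression is binarized against per-gene cohort medians (up
genes score 1 above the median, down genes below), a 3-layer network maps
score vectors to tumor probabilities, and both cohorts are evaluated with
ROC/AUC and bootstrap confidence intervals.
"""

import blcanet as b

train_x, train_labels, truth = b.generate_expression(b.SyntheticExpressionSpec(
    n_genes=1000, n_control=6, n_treatment=10, n_de_up=25, n_de_down=25, seed=7
))
test_x, test_labels, _ = b.generate_expression(b.SyntheticExpressionSpec(
    n_genes=1000, n_control=3, n_treatment=3, n_de_up=25, n_de_down=25, seed=8
))

det = b.moderated_t_table(train_x, train_labels)
fgs = b.select_feature_genes(train_x, train_labels, b.filter_degs(det),
                             b.ForestConfig(seed=7))
print(f"feature genes: {fgs.genes}")

train_scores = b.score_samples(train_x, fgs, cohort="train")
test_scores = b.score_samples(test_x, fgs, cohort="test")  # its own medians
print("train score matrix (samples x genes):")
print(train_scores.scores)

model = b.train_nn(train_scores, train_labels, b.NNConfig(seed=7))
print(f"\ntraining stopped after {model.epochs_run} epochs, "
      f"final cross-entropy {model.final_loss:.4f}")

for name, scores, labels in (("train", train_scores, train_labels),
                             ("test", test_scores, test_labels)):
    preds = b.predict_nn(model, scores)
    y = labels.groups.reindex(preds.index).values
    res = b.roc_analysis(preds["probability"].values, y, n_boot=2000, seed=7)
    conf = b.confusion_at_threshold(preds["probability"].values, y)
    print(f"{name}: AUC {res.auc:.3f} (95% CI {res.ci_low:.3f}-{res.ci_high:.3f}), "
          f"confusion TP={conf['TP']} FP={conf['FP']} TN={conf['TN']} FN={conf['FN']}")
# A score of 1 is evidence for tumor; the network's sigmoid output is the
# tumor probability, thresholded at 0.5.  The test cohort is scored with
# its own medians while the feature list and weights stay frozen.
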