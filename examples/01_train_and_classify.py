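"""Simulate a labeled contig set, train the forest, classify held-out contigs.

The synthetic dataset plants the class signal the pipeline exploits: archaeal
viruses have mostly archaea-affiliated annotations and many iterative-profile
hits, phages the opposite.  We build the 27-feature table, split 70:30,
train, and score the held-out 30% at the recommended 0.80 threshold.
"""

from arcvir import (
    SimulationConfig,
    compute_metrics,
    predict,
    simulate_dataset,
    split_train_test,
    train_forest,
)
from arcvir.pipeline import confusion_from_predictions, features_from_dataset

ds = simulate_dataset(SimulationConfig(n_per_class=150, seed=1))
table = features_from_dataset(ds)
train_tab, test_tab = split_train_test(table, ratio=0.7, seed=1)
model = train_forest(train_tab, n_trees=300, seed=1)

preds = predict(model, test_tab, threshold=0.80)
report = compute_metrics(confusion_from_predictions(preds, test_tab.labels.to_dict()))

print(f"train/test sizes: {train_tab.n}/{test_tab.n}")
print("held-out metrics at threshold 0.80:", report.rounded(3))
print("\ntop 5 features by Gini importance:")
print(model.gini_importances.sort_values(ascending=False).head(5).to_string())
print(
    "\nEach prediction probability is the fraction of trees voting archaeal;"
    "\nTPR/SPEC/ACC/MCC/FDR summarise the held-out confusion table, and the"
    "\niterative-profile (ocav) features carrying most of the importance mirrors"
    "\nthe curated archaeal-virus reference being the decisive evidence source."
)
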