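"""Robustness benchmarks: fragment-size, contamination, and subsampling grids.

Trains on clean synthetic data, then degrades the held-out set the three ways
real inputs degrade: cutting contigs into small windows (homology evidence on
broken genes is lost), spiking in 10-200 kb cellular fragments (false-positive
pressure on the FDR), and subsampling (dataset size).
"""

from arcvir import SimulationConfig, simulate_dataset, split_train_test, train_forest
from arcvir.pipeline import (
    contamination_curve,
    features_from_dataset,
    fragmentation_curve,
    subsample_curve,
)

ds = simulate_dataset(SimulationConfig(n_per_class=150, seed=4))
table = features_from_dataset(ds)
train_tab, test_tab = split_train_test(table, seed=4)
model = train_forest(train_tab, n_trees=300, seed=4)
test_ds = ds.subset(list(test_tab.data.index))

print("fragment size -> metrics (threshold 0.50)")
for size, rep in fragmentation_curve(model, test_ds, [1_000, 5_000, None], seed=4, threshold=0.5).items():
    print(f"  {'>10kb (full)' if size is None else f'{size} bp':>12}: {rep.rounded(3)}")

print("\ncontamination proportion -> metrics (threshold 0.50)")
viral_subset = test_ds.subset([c.id for c in test_ds.contigs][:40])
for p, rep in contamination_curve(model, viral_subset, [0.10, 0.50, 0.75], seed=4, threshold=0.5).items():
    print(f"  {p:>5.0%}: {rep.rounded(3)}")

print("\nsubsample fraction -> metrics")
for f, rep in subsample_curve(model, test_ds, [0.25, 0.75], seed=4).items():
    print(f"  {f:>5.0%}: {rep.rounded(3)}")

print(
    "\nMCC collapses on 1 kb fragments (few intact genes, little homology"
    "\nevidence) but survives subsampling; contaminant fragments have almost"
    "\nno viral-database hits here, so they are routed to the phage side and"
    "\nthe FDR stays flat — real cellular archaea sharing genes with their"
    "\nviruses would push it up."
)
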