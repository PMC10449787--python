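"""Run the legacy rule-based classifier and compare it with the forest.

The v1 rules call a contig archaeal when over 2/3 (category 1) or over 1/2
(category 2) of its annotated genes affiliate with archaea/archaeal viruses,
with bitscore gates (>50 homology, >40 domain, best archaeal >75 and beating
the best phage hit).
"""

from collections import Counter, defaultdict

from arcvir import SimulationConfig, simulate_dataset
from arcvir.rules_v1 import annotate_v1, classify_v1

ds = simulate_dataset(SimulationConfig(n_per_class=100, seed=2))
hits_by_contig = defaultdict(list)
for h in ds.hits:
    hits_by_contig[h.contig_id].append(h)

calls = Counter()
for contig in ds.contigs:
    res = classify_v1(contig.id, annotate_v1(hits_by_contig[contig.id]))
    truth = ds.labels[contig.id]
    called = "archaeal" if res.category in (1, 2) else "not archaeal"
    calls[(truth, called, res.category)] += 1

print("truth -> rule call (category): count")
for (truth, called, cat), n in sorted(calls.items()):
    print(f"  {truth:>14} -> {called:<12} (cat {cat}): {n}")

tp = sum(n for (t, c, _), n in calls.items() if t == "archaeal_virus" and c == "archaeal")
fp = sum(n for (t, c, _), n in calls.items() if t == "phage" and c == "archaeal")
print(f"\nrule-set recall {tp / 100:.2f}, false calls among phage {fp}")
print(
    "Category 1 calls (fraction > 2/3) dominate among true archaeal viruses;"
    "\nmisses are contigs whose annotated-gene fraction is too low for the"
    "\nfixed thresholds — the flexibility the forest was built to recover."
)
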