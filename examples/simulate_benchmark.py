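"""Benchmark the caller across sample sizes, mirroring a full study design.

Simulates a 2,000-feature population of 80 samples per group, sub-samples
3 repeat datasets at 3, 5, 10 and 20 replicates per group, runs the
wi.eBH < 0.05 caller (iqlr, K=8) on each, and aggregates precision/recall.
Runs that call nothing report missing (not zero) precision — at 3 per group
the rank test cannot reach significance, so every run is silent.
"""

import codadiff as cd

design = cd.SimDesign(n_features=2000, n_per_group=80, dispersion="low")
population = cd.simulate(design, seed=11)

records = []
for n_per_group in (3, 5, 10, 20):
    for i, rep in enumerate(cd.subsample(population, n_per_group, n_repeats=3, seed=50)):
        res = cd.run_de(rep.counts, rep.groups, "iqlr", n_instances=8, seed=100 + i)
        conf = cd.score(res.called, rep.truth)
        records.append((conf, {"transform": "iqlr", "n_per_group": n_per_group, "repeat": i}))

summary = cd.aggregate(records)
cols = ["transform", "n_per_group", "n_runs", "n_no_calls",
        "precision_mean", "recall_mean", "fdr_mean"]
print(summary.summary[cols].round(3).to_string(index=False))
print("\nprecision climbs and silence disappears as replicates increase;"
      "\nrecall is the price the method pays for its conservatism at small n")
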