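"""Imbalanced cells per individual: why sum aggregation needs normalization.

With 150 cells per case and 50 per control, the summed pseudobulk of every
gene scales with the cell count, so the sum aggregate sees a spurious
3-fold shift in all genes and its MCC collapses.  Mean aggregation divides
by each individual's own cell count and is invariant; counts-per-million
normalization rescues the sum (and makes the two aggregations identical).

Note the CPM rows: with 10% of genes strongly DE, rescaling each column by
its total leaks DE signal into null genes (a compositional effect), so CPM
trades the sum aggregate's collapse for some type-1 inflation.
"""

import scdebench as sdb

params = sdb.SimParams(n_genes=300, prop_de=0.1, n_cases=10, n_controls=10,
                       cells_per_individual_case=150,
                       cells_per_individual_control=50, master_seed=5)
ds = sdb.simulate_dataset(params)

for agg in ("mean", "sum"):
    pb = sdb.aggregate_pseudobulk(ds, agg)
    for label, matrix in (("raw", pb), ("CPM", sdb.normalize_cpm(pb))):
        res = sdb.test_pseudobulk(matrix)
        c = sdb.confusion_at_alpha(res.p_values, ds.truth, 0.05)
        print(f"Pseudobulk {agg:4s} ({label}):  MCC={sdb.mcc(c):+.3f}  "
              f"type1={sdb.type1_error(c):.3f}")
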