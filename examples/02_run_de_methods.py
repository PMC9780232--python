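"""Run the full DE method roster on one simulated dataset and score it.

Every method consumes the identical counts matrix (same checksum), so the
comparison isolates the analysis strategy.  Expect the pseudobulk tests and
GEE1 to hold the ~0.05 type-1 error while the cell-level (pseudoreplication)
tests inflate it badly — and pay for it in MCC.
"""

import scdebench as sdb

params = sdb.SimParams(n_genes=300, prop_de=0.1, master_seed=7)
ds = sdb.simulate_dataset(params)
results = sdb.run_all_methods(ds)

print(f"{'method':30s} {'MCC':>7s} {'type1':>7s} {'sens':>6s} {'failed':>6s}")
for name, res in results.items():
    c = sdb.confusion_at_alpha(res.p_values, ds.truth, alpha=0.05)
    print(f"{name:30s} {sdb.mcc(c):+7.3f} {sdb.type1_error(c):7.3f} "
          f"{sdb.sensitivity(c):6.3f} {res.n_failed:6d}")
print("\nMCC near 1 means good calls on both DE and non-DE genes; "
      "type1 is the false-positive rate among null genes at p <= 0.05.")
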