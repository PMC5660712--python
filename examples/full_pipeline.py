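"""End-to-end run at the smallest preset: simulate, train the boundary
detector, watershed + learned agglomeration, barcode consolidation,
scoring.  Takes a few minutes on one CPU.
"""

from exmtool.pipeline import RunConfig, run_experiment

res = run_experiment(RunConfig.mini(seed=1), outdir="scratch/example_run")

print("watershed H-minima sweep (split vs merge trade-off):")
print(res["watershed"][["h_min", "n_supervoxels", "rand_split", "rand_merge"]]
      .round(3).to_string(index=False))

print("\nhierarchy levels (agglomeration without barcodes):")
print(res["tree_levels"][["threshold", "n_segments", "rand_f", "vi_f"]]
      .round(3).to_string(index=False))

print("\nbarcode consolidation vs density (mean over trials):")
print(res["barcodes"].groupby("density")[["rand_f", "vi_f", "n_assigned"]]
      .mean().round(3).to_string())

print("\nsummary:", {k: round(v, 3) if isinstance(v, float) else v
                     for k, v in res["summary"].items()})
print("\nF-scores rise with barcode density: barcodes at critical locations "
      "veto false merges and join disconnected fragments of one neuron.")
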