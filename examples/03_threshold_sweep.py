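"""Robustness of the tracing conclusions over a grid of filter thresholds.

Re-runs filtering -> sharing -> ranking over an 81-point grid (coverage,
VAF, recurrence and specificity thresholds) and summarises how often each
lineage shows the maximal skin-sharing and each cluster ranks first.
"""

from mitolineage.experiments import sweep_experiment

out = sweep_experiment(seed=1)
summary = out["summary"]

print(f"{summary['n_iterations']} iterations "
      f"({summary['n_degenerate']} degenerate)\n")
print("fraction of iterations in which each lineage has maximal skin-sharing:")
print(summary["lineage"].to_string(index=False))
print("\nfraction of iterations in which each cluster ranks first:")
print(summary["rank1"].to_string(index=False))
print("\nper-threshold sensitivity (fraction of rank-1 flips when one field varies):")
print(summary["sensitivity"].to_string(index=False))
# A stable conclusion shows the myeloid lineage maximal in (nearly) all
# iterations and the precursor cluster leading the rank-1 tally.
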