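"""Neighborhood interaction testing on simulated tissue maps.

Cells are placed in a 500x500 µm field; every A cell receives a B partner
within 20 µm (attraction) while C cells are placed at random.  Neighbors
are defined by a 40 µm centroid radius and significance by label
permutation.
"""

from mitolineage import (
    SpatialSimConfig,
    analyze_sample,
    nn_distance,
    simulate_spatial_tissue,
    summarize_interactions,
)

config = SpatialSimConfig(
    n_samples=3,
    types=(("A", 40), ("B", 40), ("C", 60)),
    attraction_pairs=(("A", "B", 1.0, 20.0),),
    seed=1,
)
samples = []
for cell_map in simulate_spatial_tissue(config):
    sample = analyze_sample(cell_map, radius=40.0,
                            pairs=[("A", "B"), ("A", "C")],
                            n_permutations=1000, seed=1)
    samples.append(sample)
    for r in sample.results:
        print(f"{cell_map.sample_id} {r.from_type}->{r.to_type}: "
              f"observed {r.observed:.2f} vs null {r.null_mean:.2f}, "
              f"p={r.p:.4f} ({r.classification})")
    _, med = nn_distance(cell_map, "A", "B")
    print(f"{cell_map.sample_id} median A->B nearest-neighbor distance: {med:.1f} µm")

print("\ncross-sample summary:")
print(summarize_interactions(samples).to_string(index=False))
# The engineered A-B pairing shows up as significant attraction with short
# nearest-neighbor distances; A-C stays non-significant.
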