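"""Identify dynamic communities in a structure and pick the optimal count.

Builds a synthetic two-domain protein (two packed C-alpha clusters joined
by a short linker), runs the GNM -> dynamic distance -> Ward clustering ->
Calinski-Harabasz pipeline, and prints the CH curve over the community
sweep.  The peak of the curve is the data-driven community count; for this
fixture it should sit at k=2, matching the planted domains.
"""

import dci

fixture = dci.make_two_domain(n1=20, n2=20, gap=12.0, jitter=0.5, seed=1)
model = fixture.model
print(f"structure: {model.source_id}, {len(model)} residues")

d = dci.dynamic_distance_from_model(model, dci.GnmParameters(cutoff=7.0))
result = dci.select_communities(d, dci.ClusterSweepConfig(k_min=2, k_max=20))

print("\n  k   CH score")
for k in sorted(result.ch_by_k):
    marker = "  <- optimal" if k == result.optimal_k else ""
    print(f" {k:3d}  {result.ch_by_k[k]:9.1f}{marker}")

print(f"\noptimal community count: {result.optimal_k}")
print(f"community sizes: {[int((result.optimal_labels == c).sum()) for c in (1, 2)]}")
print("ranked CH peaks (alternative arrangements):", result.ranked_peaks)
# A single dominant peak at k=2 means the two packed domains each move as
# one coherent unit; the two linker residues join whichever domain their
# motion correlates with more strongly.
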