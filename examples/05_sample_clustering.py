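"""Cluster samples by Spearman correlation of binned fragment coverage.

Fragments are counted into 5,000-bp genome bins (a fragment increments
every bin it overlaps); samples are correlated by Spearman's rho over the
genome-wide bin vectors and clustered by average linkage on 1 - rho.
Replicates generated from the same coverage profile should pair up.
"""

from regmark import SimulationConfig, bin_fragments, cluster_samples, \
    correlation_matrix, generate

ds = generate(SimulationConfig(seed=1))
covs = [
    bin_fragments(frags, ds.chrom_sizes, 5_000, sid)
    for sid, frags in sorted(ds.fragments.items())
]
cm = correlation_matrix(covs)
print("Spearman rho matrix:")
print(cm.to_frame().round(3).to_string())

dend = cluster_samples(cm)
print("\ndendrogram (Newick):", dend.to_newick())
for profile in range(3):
    a, b = f"profile{profile}_rep0", f"profile{profile}_rep1"
    print(f"  {a} and {b} siblings: {dend.siblings(a, b)}")

# Replicates of the same planted profile correlate near 1 and merge first;
# samples from different profiles correlate near 0 and join only at the
# top of the tree.
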