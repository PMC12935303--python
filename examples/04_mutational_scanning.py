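"""In-silico deep mutational scan of a wild-type sequence.

Every single-residue substitution is scored by Delta_E, the negative change
in joint log-probability when the residue is swapped and the sequence is
reprojected into feature space.  Lower Delta_E = more probable mutant =
predicted to be better tolerated.
"""

import numpy as np

import featuredca as fd

spec = fd.ClusterSpec(
    cluster_sizes=(400, 400), L=25, q=8,
    profile_divergence=0.8, coupled_pair_fraction=0.2, seed=1,
)
aln, labels = fd.make_cluster_msa(spec)
basis = fd.fit_pca(aln, 2)
Y = fd.project(basis, aln)
params = fd.train(aln, Y)
density = fd.fit_feature_density(Y)

wt = aln.data[0]
scan = fd.full_scan(params, density, basis, wt, wild_type_id=aln.ids[0])
table = scan.table.sort_values("delta_E")
print(f"scanned {len(table)} substitutions of {scan.wild_type_id}")
print("most tolerated (lowest Delta_E):")
print(table.head(3)[["mutation", "delta_E"]].to_string(index=False))
print("most deleterious (highest Delta_E):")
print(table.tail(3)[["mutation", "delta_E"]].to_string(index=False))
# Delta_E near 0: the model sees the mutant as roughly as probable as the
# wild type.  Large positive Delta_E: the substitution violates the
# conservation/coupling constraints the model learned from the family.
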