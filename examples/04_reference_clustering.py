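"""Cluster the packaged published feature table by mode of action.

Loads the shipped 4-condition reference table (Control, and cells
treated with the microtubule stabilizer paclitaxel or the disruptors
colchicine and vinblastine; 11 amplitudes + 11 phases each), correlates
the conditions, and cuts the average-linkage tree on d = 1 − r at two
clusters.  The disruptors group together, the control sides with the
stabilizer, and the stabilizer correlates negatively with both
disruptors — the published mode-of-action structure.
"""

from phenofft import cluster_conditions, condition_correlation, \
    load_reference_features

matrix = load_reference_features()
corr = condition_correlation(matrix)
print("condition correlation matrix:")
print(corr.round(3).to_string())

result = cluster_conditions(corr, method="average", k=2)
print("\nclusters at k = 2:")
for label, members in sorted(result.members().items()):
    print(f"  cluster {label}: {', '.join(members)}")
print(f"\ncorr(PTX, CLC) = {corr.loc['PTX', 'CLC']:.3f}  "
      f"corr(PTX, VBL) = {corr.loc['PTX', 'VBL']:.3f}  (both negative)")
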