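"""Conformational clustering of CDR loops: canonical forms vs diffuse CDR3.

Generates a repertoire in the default study conditions — CDR1/CDR2 fall
into a few planted canonical conformations, CDR3 is diffuse — and runs
greedy threshold clustering at 1 Angstrom on the pairwise distance
matrices, reporting the cluster census for each region.
"""

from tcrloops import (
    GeneratorConfig,
    cluster_census,
    extract_loops,
    generate_repertoire,
    greedy_cluster,
    pairwise_distance_matrix,
)

records, truth = generate_repertoire(GeneratorConfig(n_records=60, seed=11))

for region in ("CDR1", "CDR2", "CDR3"):
    loops = extract_loops(records, "alpha", region)
    matrix = pairwise_distance_matrix(loops, ids=[r.record_id for r in records])
    census = cluster_census(greedy_cluster(matrix, tau=1.0))
    planted = len(set(truth.labels["alpha"][region]) - {-1}) or "diffuse"
    print(f"{region}-alpha: {census.count:3d} clusters of {len(records)} loops "
        f"(planted: {planted}; singleton fraction {census.singleton_fraction:.2f})")
# CDR1/CDR2 recover the handful of planted canonical forms; the diffuse
# CDR3 yields nearly one cluster per loop, the hallmark of a
# non-canonical loop.
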