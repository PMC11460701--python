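"""Co-enrichment clustering: key-code the per-RBP FLEXI subsets, compute
Gower distances, cluster by complete linkage, and compare against the
planted clusters; then re-cluster random subsets of non-FLEXI introns.
"""

import sys
from pathlib import Path

import pandas as pd
from sklearn.metrics import adjusted_rand_score

sys.path.insert(0, str(Path(__file__).parent))
from common import ensure_results, get_catalog, get_data, get_fragments

from flexiscan import cluster, detect, rbp


def main():
    data = get_data()
    catalog = get_catalog(data)
    calls = detect.call_flexis(get_fragments(data), catalog, "sim")
    sites = rbp.read_site_bed(data.paths["sites"])
    profiles = rbp.intersect_sites(catalog, sites, intron_ids=set(calls))
    ranked = rbp.rbps_with_min_flexis(profiles, min_count=30)
    results = ensure_results()

    matrix = cluster.build_keycode_matrix(profiles, list(ranked["rbp"]))
    matrix.to_csv(results / "keycode_matrix.tsv", sep="\t")
    assignment = cluster.cluster_keycode_matrix(matrix, k=3)
    memb = pd.DataFrame(sorted(assignment.clusters.items()), columns=["rbp", "cluster"])
    memb.to_csv(results / "rbp_clusters.tsv", sep="\t", index=False)
    (results / "dendrogram.nwk").write_text(cluster.linkage_to_newick(assignment) + "\n")

    truth = {
        r: c for c, mem in data.truth.rbp_cluster_members.items() for r in mem
    }
    in_truth = [r for r in matrix.index if r in truth]
    ari = adjusted_rand_score(
        [assignment.clusters[r] for r in in_truth], [truth[r] for r in in_truth]
    )
    print(f"key-code matrix: {matrix.shape[0]} row RBPs x {matrix.shape[1]} columns")
    print(f"clusters (k=3) vs planted: ARI = {ari:.3f}")
    for cid in sorted(set(assignment.clusters.values())):
        members = [r for r, c in assignment.clusters.items() if c == cid]
        print(f"  cluster {cid}: {', '.join(sorted(members))}")

    # non-FLEXI short introns: random-subset re-clustering (population is
    # small here, so this exercises the full-set fallback path)
    other = {
        i: p for i, p in rbp.intersect_sites(catalog, sites).items()
        if i not in calls and catalog[i].size_class == "short"
    }
    from collections import Counter

    counts = Counter(r for p in other.values() for r in p.rbps)
    rows = [r for r in sorted(counts) if counts[r] >= 2]
    if len(other) >= 4 and len(rows) >= 2:
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            reps = cluster.random_subset_clustering(
                other, rows, subset_size=2000, n_repeats=10, k=3, seed=7
            )
        print(f"other-short-intron re-clustering: {len(reps)} repeat(s), "
              f"{len(reps[0][0])} row RBPs retained")
    else:
        print("other-short-intron re-clustering skipped: no RBP binds >= 2 "
              "non-FLEXI short introns (only background sites there)")


if __name__ == "__main__":
    main()
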