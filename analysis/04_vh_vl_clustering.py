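#!/usr/bin/env python
"""Neighbor-joining dendrogram of the most enriched clonotype junctions.

Emulates the post-panning screen: take the top clonotypes after round 2,
align their junction amino-acid sequences pairwise (BLOSUM62 global
alignment), build identity-based distances and an NJ tree annotated with
IGHV subgroups, and report identical-sequence clusters.  Writes
results/clusters.nwk and results/cluster_report.json.
"""

import json
from pathlib import Path

from phagepan.clonotyping import repertoire_from_airr, v_subgroup
from phagepan.clustering import (
    ProteinEntry,
    annotate_and_export,
    distance_matrix,
    neighbor_joining,
)

ROOT = Path(__file__).resolve().parent.parent / "results"
TOP_N = 30


def main() -> None:
    sample = repertoire_from_airr(ROOT / "simulation" / "round2.airr.tsv", "round2")
    top = sorted(sample.counts.items(), key=lambda kv: (-kv[1], kv[0].junction_aa))
    entries = [
        ProteinEntry(
            id=f"c{i + 1}",
            chain="VH",
            sequence=key.junction_aa,
            v_subgroup=v_subgroup(key.v_gene),
        )
        for i, (key, _) in enumerate(top[:TOP_N])
    ]
    tree = neighbor_joining(distance_matrix(entries))
    newick, report = annotate_and_export(tree, entries)
    (ROOT / "clusters.nwk").write_text(newick + "\n")
    (ROOT / "cluster_report.json").write_text(json.dumps(report, indent=2))
    print(f"clustered top {len(entries)} round-2 clonotype junctions")
    print(f"{report['n_unique']} of {report['n_entries']} sequences unique "
          f"({report['unique_pct']}%); "
          f"{len(report['clusters'])} identical-sequence clusters")
    print(f"tree written to {ROOT / 'clusters.nwk'}")


if __name__ == "__main__":
    main()
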