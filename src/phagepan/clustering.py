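"""VH/VL similarity dendrograms.

Pairwise global protein alignment (BLOSUM62, affine gaps) gives
percent-identity distances d = 1 - identity/100 between the Sanger-sequenced
antibody variable regions; a neighbor-joining tree built on that matrix is
exported as Newick, with leaves annotated by IMGT V-gene subgroup and a
report of identical-sequence clusters (the unique-sequence fraction the
screen relies on when picking clonotype prototypes).
"""

from __future__ import annotations

import re
from collections import defaultdict
from dataclasses import dataclass
from io import StringIO

import numpy as np
import skbio
from Bio.Align import PairwiseAligner, substitution_matrices

__all__ = [
    "ProteinEntry",
    "DistanceMatrix",
    "pairwise_identity",
    "identity_percent",
    "distance_matrix",
    "neighbor_joining",
    "annotate_and_export",
]

_AA = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class ProteinEntry:
    """One sequenced antibody chain."""

    id: str
    chain: str  # "VH" or "VL"
    sequence: str
    v_subgroup: str = ""

    def __post_init__(self) -> None:
        bad = set(self.sequence) - _AA
        if bad:
            raise ValueError(f"{self.id}: non-amino-acid characters {sorted(bad)}")
        if self.chain not in ("VH", "VL"):
            raise ValueError(f"{self.id}: chain must be VH or VL")


@dataclass
class DistanceMatrix:
    ids: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        if self.d.shape != (len(self.ids), len(self.ids)):
            raise ValueError("distance matrix shape does not match ids")
        if not np.allclose(self.d, self.d.T) or not np.allclose(np.diag(self.d), 0):
            raise ValueError("distance matrix must be symmetric with zero diagonal")

    def to_skbio(self) -> skbio.DistanceMatrix:
        return skbio.DistanceMatrix(self.d, ids=self.ids)


def _aligner(open_gap: float = 10.0, extend_gap: float = 1.0) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -open_gap
    aligner.extend_gap_score = -extend_gap
    return aligner


def identity_percent(matches: int, aligned_length: int) -> float:
    """Percent identity from match and column counts (one-decimal convention)."""
    if aligned_length <= 0:
        raise ValueError("aligned_length must be >= 1")
    return 100.0 * matches / aligned_length


def pairwise_identity(
    a: str,
    b: str,
    open_gap: float = 10.0,
    extend_gap: float = 1.0,
) -> tuple[int, int, float]:
    """Global-alignment identity between two protein sequences.

    Returns ``(matches, aligned_length, identity_pct)`` where
    ``aligned_length`` counts alignment columns excluding terminal-gap
    columns, so unequal-length pairs get a symmetric, full-overlap
    denominator.  The highest-scoring alignment is used (Biopython's
    deterministic first path on ties).
    """
    for seq in (a, b):
        if not seq:
            raise ValueError("empty sequence")
        bad = set(seq) - _AA
        if bad:
            raise ValueError(f"non-amino-acid characters {sorted(bad)}")
    aln = _aligner(open_gap, extend_gap).align(a, b)[0]
    sa, sb = str(aln[0]), str(aln[1])
    # strip terminal-gap columns
    start = 0
    while sa[start] == "-" or sb[start] == "-":
        start += 1
    end = len(sa)
    while sa[end - 1] == "-" or sb[end - 1] == "-":
        end -= 1
    matches = sum(1 for x, y in zip(sa[start:end], sb[start:end]) if x == y)
    aligned_length = end - start
    return matches, aligned_length, identity_percent(matches, aligned_length)


def distance_matrix(entries: list[ProteinEntry]) -> DistanceMatrix:
    """All-pairs dissimilarity d = 1 - identity_pct / 100 for one chain type."""
    if len(entries) < 2:
        raise ValueError("need at least two entries")
    chains = {e.chain for e in entries}
    if len(chains) > 1:
        raise ValueError(f"mixed chain types {sorted(chains)}")
    ids = [e.id for e in entries]
    if len(set(ids)) != len(ids):
        raise ValueError("entry ids must be unique")
    n = len(entries)
    d = np.zeros((n, n))
    for i in range(n):
        for k in range(i + 1, n):
            _, _, pct = pairwise_identity(entries[i].sequence, entries[k].sequence)
            d[i, k] = d[k, i] = 1.0 - pct / 100.0
    return DistanceMatrix(ids=ids, d=d)


def neighbor_joining(dm: DistanceMatrix) -> skbio.TreeNode:
    """Classic neighbor joining (Saitou-Nei) with negative branches clamped.

    Negative branch lengths are set to zero with the deficit moved to the
    sibling branch.  For n < 3 a trivial two-leaf tree is returned.
    """
    if len(dm.ids) < 3:
        a, b = dm.ids[0], dm.ids[-1]
        half = dm.d[0, -1] / 2.0
        return skbio.TreeNode.read(StringIO(f"({a}:{half},{b}:{half});"))
    return skbio.tree.nj(dm.to_skbio(), neg_as_zero=True)


def annotate_and_export(
    tree: skbio.TreeNode, entries: list[ProteinEntry]
) -> tuple[str, dict]:
    """Newick string plus a grouping report of identical-sequence clusters.

    The report lists clusters of entries with identical sequences, the number
    of unique sequences (those occurring exactly once) and the unique
    fraction as a percentage of entries.  Leaf names gain a ``|subgroup``
    suffix when subgroup labels are present.
    """
    by_id = {e.id: e for e in entries}
    leaves = {leaf.name.split("|")[0] for leaf in tree.tips()}
    if leaves != set(by_id):
        raise ValueError("tree leaves do not match entry ids")

    clusters: dict[str, list[str]] = defaultdict(list)
    for e in entries:
        clusters[e.sequence].append(e.id)
    singleton_entries = sum(1 for ids in clusters.values() if len(ids) == 1)
    report = {
        "n_entries": len(entries),
        "n_distinct_sequences": len(clusters),
        "n_unique": singleton_entries,
        "unique_pct": round(100.0 * singleton_entries / len(entries), 1),
        "clusters": sorted(
            (sorted(ids) for ids in clusters.values() if len(ids) > 1),
            key=lambda ids: (-len(ids), ids),
        ),
    }

    annotated = tree.copy()
    for leaf in annotated.tips():
        entry = by_id[leaf.name.split("|")[0]]
        if entry.v_subgroup:
            leaf.name = f"{entry.id}|{entry.v_subgroup}"
    buf = StringIO()
    annotated.write(buf, format="newick")
    return buf.getvalue().strip(), report


def parse_subgroup(gene_name: str) -> str:
    """Subgroup label for dendrogram annotation (tolerant wrapper)."""
    m = re.match(r"^(IG[HKL]V\d+)", gene_name)
    return m.group(1) if m else gene_name
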