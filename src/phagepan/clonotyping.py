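"""Clonotype calling on antibody heavy-chain rearrangements.

A VH clonotype is the identity of a B-cell clone's rearrangement: the IGHV and
IGHJ genes, the junction segmentation (nt trimmed from the V 3' end and the J
5' end, and the length of the N-IGHD-N region), and the junction amino-acid
sequence itself.  The junction is the IMGT region from the conserved Cys at
codon 104 to the conserved Trp at codon 118, inclusive; CDRH3 is the junction
minus those two anchor residues.

The primary input path is a pre-annotated AIRR rearrangement TSV; the built-in
edit-distance gene assigner (`assign_genes`) is a convenience path for
simulated reads, not a full repertoire annotator.
"""

from __future__ import annotations

import logging
import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import edlib
import pandas as pd
from Bio.Seq import Seq

from .germline import GermlineGene

__all__ = [
    "Rearrangement",
    "ClonotypeKey",
    "RepertoireSample",
    "assign_genes",
    "extract_junction",
    "cdrh3_from_junction",
    "clonotype_key",
    "build_repertoire",
    "v_subgroup",
    "read_airr",
    "write_airr",
    "rearrangements_from_airr",
    "repertoire_from_airr",
    "AIRR_COLUMNS",
]

log = logging.getLogger(__name__)

#: Column contract for AIRR rearrangement TSV input/output.
AIRR_COLUMNS = [
    "sequence_id",
    "v_call",
    "d_call",
    "j_call",
    "junction",
    "junction_aa",
    "productive",
    "v_3p_deletion",
    "j_5p_deletion",
    "np_total_length",
]

# fraction of the aligned germline core that may mismatch before a no-call
_MAX_ERROR_FRAC = 0.2


@dataclass(frozen=True)
class ClonotypeKey:
    """Value object identifying a B-cell clone's VH rearrangement."""

    v_gene: str
    j_gene: str
    v_3p_deletion: int
    j_5p_deletion: int
    ndn_length: int
    junction_aa: str

    def __post_init__(self) -> None:
        if not 5 <= len(self.junction_aa) <= 32:
            raise ValueError(
                f"junction_aa length {len(self.junction_aa)} outside [5, 32]"
            )

    @property
    def cdrh3_aa(self) -> str:
        return self.junction_aa[1:-1]


@dataclass
class Rearrangement:
    """One annotated read."""

    sequence_id: str
    v_call: str | None
    j_call: str | None
    junction_nt: str | None
    junction_aa: str | None
    v_3p_deletion: int | None
    j_5p_deletion: int | None
    ndn_length: int | None
    productive: bool
    round_label: str = ""
    d_call: str | None = None

    @property
    def identified(self) -> bool:
        return self.v_call is not None and self.j_call is not None


@dataclass
class RepertoireSample:
    """Clonotype -> read-count table for one panning stage.

    ``total_identified`` is the frequency denominator: the number of reads
    with an identified rearrangement (it may exceed the sum of counts when
    non-productive identified reads were excluded from clonotyping).
    """

    label: str
    counts: Counter[ClonotypeKey] = field(default_factory=Counter)
    total_identified: int = 0

    def __post_init__(self) -> None:
        if any(c < 1 for c in self.counts.values()):
            raise ValueError("all clonotype counts must be >= 1")
        if sum(self.counts.values()) > self.total_identified:
            raise ValueError("counts exceed total_identified")

    @property
    def n_reads(self) -> int:
        return sum(self.counts.values())

    @property
    def n_clonotypes(self) -> int:
        return len(self.counts)

    def frequency_pct(self, key: ClonotypeKey) -> float:
        """Frequency as percentage of reads with identified rearrangements."""
        return 100.0 * self.counts.get(key, 0) / self.total_identified

    def frequencies_pct(self) -> dict[ClonotypeKey, float]:
        return {k: 100.0 * c / self.total_identified for k, c in self.counts.items()}


def v_subgroup(gene_name: str) -> str:
    """IMGT V-gene subgroup: locus + 'V' + leading numeric block.

    >>> v_subgroup("IGHV5-9-3")
    'IGHV5'
    """
    m = re.match(r"^(IG[HKL]V\d+)", gene_name)
    if m is None:
        raise ValueError(f"{gene_name!r} is not an IMGT V gene name")
    return m.group(1)


def cdrh3_from_junction(junction_aa: str) -> str:
    """CDRH3 = junction minus the C104 and W118 anchor residues."""
    if len(junction_aa) < 2:
        raise ValueError("junction too short to strip anchors")
    return junction_aa[1:-1]


def _translate(nt: str) -> str:
    return str(Seq(nt).translate())


def extract_junction(
    read_nt: str,
    v: GermlineGene,
    j: GermlineGene,
    j_core_start: int,
) -> tuple[str, str | None, str | None]:
    """Extract the IMGT junction (codons 104-118 inclusive) from a read.

    ``j_core_start`` is the read offset where the J anchor (Trp codon) begins.
    Returns ``(junction_nt, junction_aa, cdrh3_aa)``; the amino-acid fields
    are ``None`` when the junction is out of frame (flagged non-productive by
    the caller).
    """
    if v.anchor_offset is None or j.anchor_offset is None:
        raise ValueError("V and J genes must carry junction anchors")
    junction_nt = read_nt[v.anchor_offset : j_core_start + 3]
    if len(junction_nt) % 3 != 0:
        return junction_nt, None, None
    aa = _translate(junction_nt)
    return junction_nt, aa, aa[1:-1]


def _best_gene(
    read: str, genes: list[GermlineGene], segment: str
) -> tuple[GermlineGene, int] | None:
    """Best edit-distance match of germline core against the read end.

    V cores (start of gene through the Cys codon) are matched against the read
    prefix; J cores (Trp codon through FR4) against the read suffix, by
    aligning reversed sequences.  Ties break to the lexicographically smallest
    gene name.
    """
    best: tuple[int, str, GermlineGene] | None = None
    for g in genes:
        if g.segment != segment or g.anchor_offset is None:
            continue
        if segment == "V":
            core, target = g.sequence[: g.anchor_offset + 3], read
        else:
            core, target = g.sequence[g.anchor_offset :][::-1], read[::-1]
        res = edlib.align(core, target, mode="SHW", task="distance")
        d = res["editDistance"]
        if d < 0:
            continue
        cand = (d, g.name, g)
        if best is None or cand[:2] < best[:2]:
            if best is not None and d == best[0]:
                log.debug("gene-call tie at distance %d: %s vs %s", d, g.name, best[1])
            best = cand
    if best is None:
        return None
    gene = best[2]
    core_len = (
        gene.anchor_offset + 3 if segment == "V" else len(gene.sequence) - gene.anchor_offset
    )
    if best[0] > _MAX_ERROR_FRAC * core_len:
        return None
    return gene, best[0]


def assign_genes(
    read_nt: str,
    germline: list[GermlineGene],
    sequence_id: str = "",
    round_label: str = "",
) -> Rearrangement | None:
    """Annotate a read against a germline set; ``None`` on no-call.

    The V call is the best-scoring alignment of each V core (through the Cys
    anchor) against the read prefix and the J call likewise against the read
    suffix.  Trimming is then inferred by maximal exact germline extension
    into the junction interior (V side first, then J), and the unassigned
    middle is the N-D-N region.
    """
    read_nt = read_nt.strip().upper()
    if len(read_nt) < 50:
        raise ValueError(f"read shorter than 50 nt ({len(read_nt)})")
    if not any(g.segment == "V" for g in germline) or not any(
        g.segment == "J" for g in germline
    ):
        raise ValueError("germline must contain at least one V and one J gene")

    v_hit = _best_gene(read_nt, germline, "V")
    j_hit = _best_gene(read_nt, germline, "J")
    if v_hit is None or j_hit is None:
        return None
    v, j = v_hit[0], j_hit[0]

    v_core_len = v.anchor_offset + 3  # through the Cys codon
    j_core_len = len(j.sequence) - j.anchor_offset  # Trp codon through FR4
    j_core_start = len(read_nt) - j_core_len
    if j_core_start < v_core_len:
        return None  # segments overlap: not a plausible rearrangement

    interior = read_nt[v_core_len:j_core_start]
    v_tail = v.sequence[v.anchor_offset + 3 :]
    j_head = j.sequence[: j.anchor_offset]

    v_keep = 0
    while (
        v_keep < min(len(v_tail), len(interior))
        and interior[v_keep] == v_tail[v_keep]
    ):
        v_keep += 1
    j_keep = 0
    budget = len(interior) - v_keep
    while (
        j_keep < min(len(j_head), budget)
        and interior[len(interior) - 1 - j_keep] == j_head[len(j_head) - 1 - j_keep]
    ):
        j_keep += 1

    junction_nt, junction_aa, _ = extract_junction(read_nt, v, j, j_core_start)
    productive = (
        junction_aa is not None
        and "*" not in junction_aa
        and junction_aa.startswith("C")
        and junction_aa.endswith("W")
    )
    return Rearrangement(
        sequence_id=sequence_id,
        v_call=v.name,
        j_call=j.name,
        junction_nt=junction_nt,
        junction_aa=junction_aa,
        v_3p_deletion=len(v_tail) - v_keep,
        j_5p_deletion=len(j_head) - j_keep,
        ndn_length=len(interior) - v_keep - j_keep,
        productive=productive,
        round_label=round_label,
    )


def clonotype_key(rearr: Rearrangement) -> ClonotypeKey:
    """Collapse a fully annotated rearrangement to its clonotype identity.

    Reads differing only by synonymous junction-nt changes with identical
    segmentation map to the same key; identical junction aa with different
    segmentation maps to distinct keys.  D-gene identity is deliberately not
    part of the key — only the N-D-N length is.
    """
    for name in (
        "v_call",
        "j_call",
        "junction_aa",
        "v_3p_deletion",
        "j_5p_deletion",
        "ndn_length",
    ):
        if getattr(rearr, name) is None:
            raise ValueError(f"rearrangement missing field {name!r}")
    return ClonotypeKey(
        v_gene=rearr.v_call,
        j_gene=rearr.j_call,
        v_3p_deletion=rearr.v_3p_deletion,
        j_5p_deletion=rearr.j_5p_deletion,
        ndn_length=rearr.ndn_length,
        junction_aa=rearr.junction_aa,
    )


def build_repertoire(
    rearrs: list[Rearrangement],
    label: str,
    productive_only: bool = True,
) -> RepertoireSample:
    """Aggregate annotated reads into a clonotype count table.

    ``total_identified`` counts reads with identified V and J calls; this is
    the denominator of all frequencies.  Non-productive identified reads are
    excluded from clonotype counts (default) but still counted in the
    denominator only when ``productive_only`` is False.
    """
    if not rearrs:
        raise ValueError("no rearrangements given")
    labels = {r.round_label for r in rearrs if r.round_label}
    if len(labels) > 1:
        raise ValueError(f"mixed round labels in one sample: {sorted(labels)}")
    identified = [r for r in rearrs if r.identified]
    if productive_only:
        usable = [r for r in identified if r.productive]
    else:
        usable = identified
    counts: Counter[ClonotypeKey] = Counter(clonotype_key(r) for r in usable)
    return RepertoireSample(
        label=label, counts=counts, total_identified=len(usable)
    )


# ---------------------------------------------------------------------------
# AIRR TSV I/O


def read_airr(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sequence_id": str})
    missing = [c for c in AIRR_COLUMNS if c not in df.columns and c != "d_call"]
    if missing:
        raise ValueError(f"{path}: missing AIRR columns {missing}")
    return df


def write_airr(rearrs: list[Rearrangement], path: str | Path) -> None:
    rows = [
        {
            "sequence_id": r.sequence_id,
            "v_call": r.v_call,
            "d_call": r.d_call or "",
            "j_call": r.j_call,
            "junction": r.junction_nt,
            "junction_aa": r.junction_aa,
            "productive": "T" if r.productive else "F",
            "v_3p_deletion": r.v_3p_deletion,
            "j_5p_deletion": r.j_5p_deletion,
            "np_total_length": r.ndn_length,
        }
        for r in rearrs
    ]
    pd.DataFrame(rows, columns=AIRR_COLUMNS).to_csv(path, sep="\t", index=False)


def rearrangements_from_airr(
    df: pd.DataFrame, round_label: str = ""
) -> list[Rearrangement]:
    out = []
    for row in df.itertuples(index=False):
        productive = str(row.productive).strip().upper() in ("T", "TRUE", "1")
        out.append(
            Rearrangement(
                sequence_id=str(row.sequence_id),
                v_call=row.v_call if pd.notna(row.v_call) else None,
                j_call=row.j_call if pd.notna(row.j_call) else None,
                junction_nt=row.junction if pd.notna(row.junction) else None,
                junction_aa=row.junction_aa if pd.notna(row.junction_aa) else None,
                v_3p_deletion=int(row.v_3p_deletion),
                j_5p_deletion=int(row.j_5p_deletion),
                ndn_length=int(row.np_total_length),
                productive=productive,
                round_label=round_label,
            )
        )
    return out


def repertoire_from_airr(
    path: str | Path, label: str, productive_only: bool = True
) -> RepertoireSample:
    """Read an AIRR TSV and build the round's clonotype table."""
    df = read_airr(path)
    return build_repertoire(
        rearrangements_from_airr(df, label), label, productive_only=productive_only
    )
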