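"""Synthetic germline immunoglobulin gene sets.

Builds small IMGT-style V/D/J gene collections with the conserved junction
anchors every downstream step relies on: each V gene ends in a region
containing the conserved Cys codon (IMGT position 104) plus a short germline
tail that V(D)J recombination may trim, and each J gene carries the conserved
Trp codon (IMGT position 118) preceded by a short trimmable head and followed
by a framework-4 stub.  Subgroup composition of the V genes follows the skewed
IGHV usage observed in immunized-mouse scFv libraries (IGHV1/IGHV5/IGHV14
dominant).
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np

__all__ = [
    "GermlineGene",
    "DEFAULT_SUBGROUP_WEIGHTS",
    "make_germline_set",
    "V_TAIL_NT",
    "J_HEAD_NT",
]

# nt of germline sequence 3' of the Cys codon (V) / 5' of the Trp codon (J)
# that recombination may trim; both multiples of 3 are not required.
V_TAIL_NT = 6
J_HEAD_NT = 6

#: Default IGHV subgroup usage: the three dominant subgroups of the immunized
#: mouse heavy-chain repertoire, remainder spread uniformly.
DEFAULT_SUBGROUP_WEIGHTS: dict[str, float] = {
    "IGHV1": 0.37,
    "IGHV5": 0.33,
    "IGHV14": 0.11,
    "IGHV2": 0.0475,
    "IGHV3": 0.0475,
    "IGHV6": 0.0475,
    "IGHV8": 0.0475,
}

_STOP_CODONS = {"TAA", "TAG", "TGA"}
_NT = np.array(list("ACGT"))
_CYS_CODONS = ("TGT", "TGC")


@dataclass(frozen=True)
class GermlineGene:
    """One germline gene segment.

    Parameters
    ----------
    name
        IMGT-style label, e.g. ``"IGHV5-2"``.
    subgroup
        Subgroup parsed from the name (``"IGHV5"``); prefix of ``name``.
    segment
        One of ``"V"``, ``"D"``, ``"J"``.
    sequence
        Nucleotide sequence over {A, C, G, T}.
    anchor_offset
        0-based offset of the first nt of the conserved anchor codon
        (Cys 104 for V, Trp 118 for J); ``None`` for D genes.
    """

    name: str
    subgroup: str
    segment: str
    sequence: str
    anchor_offset: int | None = None

    def __post_init__(self) -> None:
        if self.segment not in ("V", "D", "J"):
            raise ValueError(f"segment must be V/D/J, got {self.segment!r}")
        if re.search(r"[^ACGT]", self.sequence):
            raise ValueError(f"{self.name}: sequence has non-ACGT characters")
        if not self.name.startswith(self.subgroup):
            raise ValueError(f"{self.name}: subgroup {self.subgroup!r} is not a prefix")
        if self.anchor_offset is not None:
            if not 0 <= self.anchor_offset <= len(self.sequence) - 3:
                raise ValueError(f"{self.name}: anchor_offset out of bounds")
            if self.anchor_offset % 3 != 0:
                raise ValueError(f"{self.name}: anchor not in reading frame")

    @property
    def anchor_codon(self) -> str | None:
        if self.anchor_offset is None:
            return None
        return self.sequence[self.anchor_offset : self.anchor_offset + 3]


def _apportion(n: int, weights: dict[str, float]) -> dict[str, int]:
    """Largest-remainder apportionment of n genes over subgroups (±1 exact)."""
    labels = sorted(weights)
    total = sum(weights.values())
    quotas = {k: n * weights[k] / total for k in labels}
    counts = {k: int(np.floor(quotas[k])) for k in labels}
    short = n - sum(counts.values())
    by_rem = sorted(labels, key=lambda k: (-(quotas[k] - counts[k]), k))
    for k in by_rem[:short]:
        counts[k] += 1
    return counts


def _random_codons(rng: np.random.Generator, n: int) -> str:
    """n random codons, none of them stop codons."""
    out = []
    while len(out) < n:
        codon = "".join(rng.choice(_NT, 3))
        if codon not in _STOP_CODONS:
            out.append(codon)
    return "".join(out)


def make_germline_set(
    n_v: int,
    n_d: int,
    n_j: int,
    seed: int,
    subgroup_weights: dict[str, float] | None = None,
) -> list[GermlineGene]:
    """Generate a deterministic synthetic germline gene set.

    V genes are distributed over IGHV subgroups by largest-remainder
    apportionment of ``subgroup_weights`` (so the census matches the weights
    within one gene), each ending with a conserved Cys codon followed by a
    ``V_TAIL_NT``-nt trimmable germline tail.  J genes start with a
    ``J_HEAD_NT``-nt trimmable head, then the conserved Trp codon (TGG) and a
    framework-4 stub.  D genes are short untracked segments (their identity is
    not part of the clonotype definition; only N-D-N length is).
    """
    if n_v < 1 or n_d < 1 or n_j < 1:
        raise ValueError("all segment counts must be >= 1")
    weights = subgroup_weights or DEFAULT_SUBGROUP_WEIGHTS
    rng = np.random.default_rng(seed)
    genes: list[GermlineGene] = []

    v_core_codons = 87  # FR1-FR3 stand-in, ~261 nt before the Cys codon
    counts = _apportion(n_v, weights)
    for subgroup in sorted(counts):
        for i in range(counts[subgroup]):
            core = _random_codons(rng, v_core_codons)
            cys = _CYS_CODONS[int(rng.integers(len(_CYS_CODONS)))]
            tail = "".join(rng.choice(_NT, V_TAIL_NT))
            genes.append(
                GermlineGene(
                    name=f"{subgroup}-{i + 1}",
                    subgroup=subgroup,
                    segment="V",
                    sequence=core + cys + tail,
                    anchor_offset=3 * v_core_codons,
                )
            )

    for i in range(n_d):
        length = int(rng.integers(10, 21))
        genes.append(
            GermlineGene(
                name=f"IGHD{i + 1}-1",
                subgroup=f"IGHD{i + 1}",
                segment="D",
                sequence="".join(rng.choice(_NT, length)),
            )
        )

    fr4_codons = 11
    for i in range(n_j):
        head = "".join(rng.choice(_NT, J_HEAD_NT))
        fr4 = _random_codons(rng, fr4_codons)
        genes.append(
            GermlineGene(
                name=f"IGHJ{i + 1}",
                subgroup=f"IGHJ{i + 1}",
                segment="J",
                sequence=head + "TGG" + fr4,
                anchor_offset=J_HEAD_NT,
            )
        )
    return genes
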