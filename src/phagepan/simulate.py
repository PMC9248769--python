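"""Synthetic immune-library and cellular-panning simulator.

Emulates the data-generating process behind an immunized-mouse scFv
phage-display campaign: a moderately uneven immune library (log-normal
clonotype abundances, bell-shaped CDRH3 length law, skewed IGHV subgroup
usage), followed by rounds of depletion on off-target cells and positive
selection on target cells.  Selection is single-locus multiplicative per
round: with per-clonotype target fitness t_i and off-target fitness u_i, the
effective weight is w_i = t_i / u_i and the post-round expected frequency is

    p_i' = p_i * w_i / sum_j p_j * w_j,

after which reads are drawn multinomially at the configured depth.  The
simulator emits the same formats the analysis modules consume (reads as
FASTA, ground-truth annotations as AIRR TSV) plus a truth table of expected
per-round frequencies for parameter-recovery checks.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .clonotyping import ClonotypeKey, RepertoireSample
from .germline import DEFAULT_SUBGROUP_WEIGHTS, GermlineGene, J_HEAD_NT, V_TAIL_NT

__all__ = [
    "PanningConfig",
    "TruthTable",
    "simulate_library",
    "simulate_panning_round",
    "select",
    "simulate_campaign",
    "emit_reads",
]

log = logging.getLogger(__name__)

_STOP_CODONS = {"TAA", "TAG", "TGA"}
_NT = np.array(list("ACGT"))


@dataclass(frozen=True)
class PanningConfig:
    """Study conditions for one simulated campaign.

    Defaults reproduce, at desk scale, the statistical structure of the
    immunized-mouse scFv library and its two-round depletion + selection
    panning: log-normal abundances whose spread gives evenness ~0.89 at a
    50,000-read subsample, CDRH3 amino-acid lengths 5 + Binomial(14, 0.5)
    (bell-shaped, mean 12), dominant IGHV1/IGHV5/IGHV14 subgroups, and
    dispersed selection fitness that collapses diversity and evenness over
    two rounds.
    """

    n_clonotypes: int = 5000
    freq_sigma: float = 1.45
    cdrh3_length_n: int = 14
    cdrh3_length_p: float = 0.5
    cdrh3_length_min: int = 5
    subgroup_weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SUBGROUP_WEIGHTS)
    )
    target_fitness_sigma: float = 1.5
    offtarget_fitness_sigma: float = 0.5
    n_rounds: int = 2
    read_depth: int = 50_000
    error_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_clonotypes < 1:
            raise ValueError("n_clonotypes must be >= 1")
        if self.n_rounds < 0:
            raise ValueError("n_rounds must be >= 0")
        if self.read_depth < 1:
            raise ValueError("read_depth must be >= 1")
        if not 0.0 <= self.error_rate <= 0.1:
            raise ValueError("error_rate must lie in [0, 0.1]")
        total = sum(self.subgroup_weights.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"subgroup weights sum to {total}, not 1")


@dataclass
class TruthTable:
    """Ground truth for every simulated clonotype.

    ``table`` has one row per clonotype: the clonotype-key fields, the full
    rearranged nucleotide sequence, initial frequency, target fitness ``w``,
    off-target fitness ``u``, and expected frequency after each round
    (columns ``freq_round_0`` = library, ``freq_round_1``, ...).
    """

    keys: list[ClonotypeKey]
    table: pd.DataFrame

    def expected_freqs(self, round_index: int) -> np.ndarray:
        return self.table[f"freq_round_{round_index}"].to_numpy()

    def key_of(self, row_index: int) -> ClonotypeKey:
        return self.keys[row_index]


def _draw_junction(
    rng: np.random.Generator,
    v: GermlineGene,
    j: GermlineGene,
    length_aa: int,
) -> tuple[str, int, int, int]:
    """Draw one junction of exactly ``length_aa`` residues.

    Returns ``(junction_nt, v_3p_deletion, j_5p_deletion, ndn_length)`` with
    segmentation already canonicalized by maximal germline extension, so
    error-free re-annotation reproduces it exactly.  N-region nucleotides are
    uniform over {A,C,G,T}, redrawn until the junction translation carries no
    stop codon (phage-displayed clones are productive by construction).
    """
    v_tail = v.sequence[v.anchor_offset + 3 :]
    j_head = j.sequence[: j.anchor_offset]
    interior_nt = 3 * length_aa - 6  # junction minus the two anchor codons
    cys = v.anchor_codon
    trp = j.anchor_codon
    for _ in range(200):
        v_keep = int(rng.integers(0, min(V_TAIL_NT, interior_nt) + 1))
        j_keep = int(rng.integers(0, min(J_HEAD_NT, interior_nt - v_keep) + 1))
        ndn = "".join(rng.choice(_NT, interior_nt - v_keep - j_keep))
        interior = v_tail[:v_keep] + ndn + (j_head[len(j_head) - j_keep :] if j_keep else "")
        junction_nt = cys + interior + trp
        aa = str(Seq(junction_nt).translate())
        if "*" in aa:
            continue
        # canonical segmentation: maximal exact germline extension, V first
        ck = 0
        while ck < min(len(v_tail), len(interior)) and interior[ck] == v_tail[ck]:
            ck += 1
        cj = 0
        budget = len(interior) - ck
        while (
            cj < min(len(j_head), budget)
            and interior[len(interior) - 1 - cj] == j_head[len(j_head) - 1 - cj]
        ):
            cj += 1
        return (
            junction_nt,
            len(v_tail) - ck,
            len(j_head) - cj,
            len(interior) - ck - cj,
        )
    raise RuntimeError("could not draw a stop-free junction")


def simulate_library(
    cfg: PanningConfig, germline: list[GermlineGene]
) -> tuple[TruthTable, RepertoireSample]:
    """Draw an immune library and its initial sequenced sample.

    Clonotype keys are built by drawing a V gene (per subgroup weights), a J
    gene (uniform), a CDRH3 length from the bell-shaped law, and a junction
    with canonical segmentation.  Abundances are log-normal, normalized; the
    returned sample is a multinomial read draw of size ``read_depth``.
    Expected post-selection frequencies for every configured round are
    recorded in the truth table.
    """
    rng = np.random.default_rng(cfg.seed)
    v_genes = [g for g in germline if g.segment == "V"]
    j_genes = sorted(
        (g for g in germline if g.segment == "J"), key=lambda g: g.name
    )
    if not v_genes or not j_genes:
        raise ValueError("germline must contain V and J genes")

    by_subgroup: dict[str, list[GermlineGene]] = {}
    for g in v_genes:
        by_subgroup.setdefault(g.subgroup, []).append(g)
    subgroups = [s for s in cfg.subgroup_weights if s in by_subgroup]
    weights = np.array([cfg.subgroup_weights[s] for s in subgroups])
    weights = weights / weights.sum()

    if cfg.n_clonotypes > cfg.read_depth:
        log.warning(
            "n_clonotypes (%d) exceeds read_depth (%d): many clonotypes will "
            "be unobserved",
            cfg.n_clonotypes,
            cfg.read_depth,
        )

    keys: list[ClonotypeKey] = []
    rows: list[dict] = []
    seen: set[ClonotypeKey] = set()
    while len(keys) < cfg.n_clonotypes:
        sub = subgroups[int(rng.choice(len(subgroups), p=weights))]
        v = by_subgroup[sub][int(rng.integers(len(by_subgroup[sub])))]
        j = j_genes[int(rng.integers(len(j_genes)))]
        length_aa = cfg.cdrh3_length_min + 2 + int(
            rng.binomial(cfg.cdrh3_length_n, cfg.cdrh3_length_p)
        )  # junction length = CDRH3 length + 2 anchors
        junction_nt, dv, dj, ndn = _draw_junction(rng, v, j, length_aa)
        aa = str(Seq(junction_nt).translate())
        key = ClonotypeKey(
            v_gene=v.name,
            j_gene=j.name,
            v_3p_deletion=dv,
            j_5p_deletion=dj,
            ndn_length=ndn,
            junction_aa=aa,
        )
        if key in seen:
            continue
        seen.add(key)
        keys.append(key)
        full_nt = (
            v.sequence[: v.anchor_offset]  # V before the Cys codon
            + junction_nt
            + j.sequence[j.anchor_offset + 3 :]  # J after the Trp codon
        )
        rows.append(
            {
                "v_gene": v.name,
                "j_gene": j.name,
                "v_3p_deletion": dv,
                "j_5p_deletion": dj,
                "ndn_length": ndn,
                "junction_aa": aa,
                "sequence_nt": full_nt,
            }
        )

    abundance = rng.lognormal(0.0, cfg.freq_sigma, cfg.n_clonotypes)
    p0 = abundance / abundance.sum()
    t = rng.lognormal(0.0, cfg.target_fitness_sigma, cfg.n_clonotypes)
    u = rng.lognormal(0.0, cfg.offtarget_fitness_sigma, cfg.n_clonotypes)
    w = t / u

    table = pd.DataFrame(rows)
    table["initial_freq"] = p0
    table["target_fitness"] = t
    table["offtarget_fitness"] = u
    table["fitness"] = w
    p = p0.copy()
    table["freq_round_0"] = p
    for r in range(1, cfg.n_rounds + 1):
        p = select(p, w)
        table[f"freq_round_{r}"] = p

    counts = rng.multinomial(cfg.read_depth, p0)
    sample = RepertoireSample(
        label="library",
        counts=Counter(
            {keys[i]: int(c) for i, c in enumerate(counts) if c > 0}
        ),
        total_identified=int(counts.sum()),
    )
    return TruthTable(keys=keys, table=table), sample


def select(p: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Expected post-selection frequencies p_i * w_i / sum p_j * w_j."""
    p = np.asarray(p, dtype=float)
    w = np.asarray(w, dtype=float)
    if p.size == 0:
        raise ValueError("empty frequency vector")
    if np.any(w <= 0):
        raise ValueError("all fitness weights must be > 0")
    if abs(p.sum() - 1.0) > 1e-6:
        raise ValueError(f"frequencies sum to {p.sum()}, not 1")
    mass = p * w
    total = mass.sum()
    if total <= 0:
        raise ValueError("zero total selective mass")
    return mass / total


def simulate_panning_round(
    sample_freqs: dict[ClonotypeKey, float],
    fitness: dict[ClonotypeKey, float],
    depth: int,
    seed: int,
    label: str = "round",
) -> RepertoireSample:
    """One depletion + selection round followed by multinomial sequencing.

    ``fitness`` maps each clonotype to its effective weight t_i / u_i (target
    over off-target fitness); depletion is folded into that ratio.
    """
    if not sample_freqs:
        raise ValueError("empty input sample")
    keys = sorted(sample_freqs, key=lambda k: (k.v_gene, k.j_gene, k.junction_aa,
                                               k.v_3p_deletion, k.j_5p_deletion,
                                               k.ndn_length))
    p = np.array([sample_freqs[k] for k in keys])
    w = np.array([fitness[k] for k in keys])
    p_post = select(p, w)
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(depth, p_post)
    return RepertoireSample(
        label=label,
        counts=Counter({keys[i]: int(c) for i, c in enumerate(counts) if c > 0}),
        total_identified=int(counts.sum()),
    )


def simulate_campaign(
    cfg: PanningConfig, germline: list[GermlineGene]
) -> tuple[TruthTable, list[RepertoireSample]]:
    """Full campaign: library sample plus one sample per panning round."""
    truth, library = simulate_library(cfg, germline)
    rng = np.random.default_rng(cfg.seed + 1)
    samples = [library]
    for r in range(1, cfg.n_rounds + 1):
        p = truth.expected_freqs(r)
        counts = rng.multinomial(cfg.read_depth, p)
        samples.append(
            RepertoireSample(
                label=f"round{r}",
                counts=Counter(
                    {truth.keys[i]: int(c) for i, c in enumerate(counts) if c > 0}
                ),
                total_identified=int(counts.sum()),
            )
        )
    return truth, samples


def _mutate(rng: np.random.Generator, seq: str, error_rate: float) -> str:
    if error_rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hits = np.flatnonzero(rng.random(arr.size) < error_rate)
    for i in hits:
        choices = [bytes([b]) for b in b"ACGT" if bytes([b]) != arr[i]]
        arr[i] = choices[int(rng.integers(3))]
    return arr.tobytes().decode()


def emit_reads(
    sample: RepertoireSample,
    truth: TruthTable,
    germline: list[GermlineGene],
    error_rate: float,
    seed: int,
    fasta_path: str | Path,
    airr_path: str | Path,
) -> None:
    """Write one nucleotide read per sampled occurrence plus truth AIRR TSV.

    Reads are the assembled V + N-D-N + J sequences with per-nt substitution
    errors at ``error_rate``; the AIRR TSV carries the ground-truth clonotype
    fields (not re-annotated calls).
    """
    if not 0.0 <= error_rate <= 0.1:
        raise ValueError("error_rate must lie in [0, 0.1]")
    rng = np.random.default_rng(seed)
    index = {k: i for i, k in enumerate(truth.keys)}
    fasta_path, airr_path = Path(fasta_path), Path(airr_path)
    try:
        with open(fasta_path, "w") as fa, open(airr_path, "w") as tsv:
            tsv.write(
                "sequence_id\tv_call\td_call\tj_call\tjunction\tjunction_aa\t"
                "productive\tv_3p_deletion\tj_5p_deletion\tnp_total_length\n"
            )
            n = 0
            for key in sorted(
                sample.counts,
                key=lambda k: (k.v_gene, k.j_gene, k.junction_aa,
                               k.v_3p_deletion, k.j_5p_deletion, k.ndn_length),
            ):
                row = truth.table.iloc[index[key]]
                for _ in range(sample.counts[key]):
                    n += 1
                    sid = f"{sample.label}_{n:07d}"
                    read = _mutate(rng, row["sequence_nt"], error_rate)
                    fa.write(f">{sid}\n{read}\n")
                    tsv.write(
                        "\t".join(
                            [
                                sid,
                                key.v_gene,
                                "",
                                key.j_gene,
                                _junction_nt_of(row, germline),
                                key.junction_aa,
                                "T",
                                str(key.v_3p_deletion),
                                str(key.j_5p_deletion),
                                str(key.ndn_length),
                            ]
                        )
                        + "\n"
                    )
    except OSError as exc:
        raise OSError(f"failed writing simulated reads to {exc.filename}") from exc


def _junction_nt_of(row: pd.Series, germline: list[GermlineGene]) -> str:
    v = next(g for g in germline if g.name == row["v_gene"])
    j = next(g for g in germline if g.name == row["j_gene"])
    seq = row["sequence_nt"]
    j_core_len = len(j.sequence) - j.anchor_offset
    return seq[v.anchor_offset : len(seq) - j_core_len + 3]
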