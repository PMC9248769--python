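"""Cross-round clonotype frequency tracking and fold enrichment.

Each clonotype's frequency (percent of reads with identified rearrangements)
is followed from the unselected library through the panning rounds.  Fold
enrichment is the ratio of last-round to first-round frequency, computed only
for clonotypes detected in both datasets (no pseudocounts by default: a fold
change for an unobserved clonotype would be fabricated).  Final-round
frequencies place clonotypes into the <0.1% / 0.1-1% / >1% tiers used to
judge how exhaustively the enriched repertoire was screened.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .clonotyping import ClonotypeKey, RepertoireSample

__all__ = [
    "EnrichmentRecord",
    "track_clonotypes",
    "fold_enrichment",
    "format_fold",
    "classify",
    "tier",
    "scatter_table",
]

TIERS = ("<0.1%", "0.1–1%", ">1%")


@dataclass
class EnrichmentRecord:
    """Frequency trajectory of one clonotype across panning rounds."""

    clonotype: ClonotypeKey
    freq_pct_by_round: dict[str, float | None]
    fold_change: float | None
    status: str  # enriched / depleted / flat / not_evaluable
    tier_final: str


def fold_enrichment(freq_first_pct: float, freq_last_pct: float) -> float:
    """freq_last / freq_first; values < 1 are depletions."""
    if freq_first_pct is None or freq_last_pct is None:
        raise ValueError("fold enrichment undefined for unobserved frequencies")
    if freq_first_pct <= 0 or freq_last_pct <= 0:
        raise ValueError("fold enrichment requires positive frequencies")
    return freq_last_pct / freq_first_pct


def format_fold(fold: float) -> str:
    """Display rounding: nearest integer for fold >= 10, one decimal below."""
    if fold >= 10:
        return f"{int(math.floor(fold + 0.5)):,}"
    return f"{fold:.1f}"


def tier(freq_pct: float) -> str:
    """Final-frequency tier: '<0.1%', '0.1-1%' or '>1%'."""
    if freq_pct > 1.0:
        return TIERS[2]
    if freq_pct > 0.1:
        return TIERS[1]
    return TIERS[0]


def classify(
    fold_change: float | None, flat_band: tuple[float, float] = (0.5, 2.0)
) -> str:
    """enriched / depleted / flat by the fold change, not_evaluable on NA."""
    lower, upper = flat_band
    if not (0 < lower <= upper):
        raise ValueError(f"malformed flat band {flat_band}")
    if fold_change is None:
        return "not_evaluable"
    if fold_change > upper:
        return "enriched"
    if fold_change < lower:
        return "depleted"
    return "flat"


def track_clonotypes(
    samples: list[RepertoireSample],
    flat_band: tuple[float, float] = (0.5, 2.0),
    pseudo_floor: bool = False,
) -> list[EnrichmentRecord]:
    """Trajectories for the union of clonotypes across ordered rounds.

    Frequencies are percent of identified reads per round; None where a
    clonotype is unobserved.  With ``pseudo_floor`` a missing first-round
    frequency is replaced by one read over that round's denominator so a
    (lower-bound) fold change can still be quoted.
    """
    if len(samples) < 2:
        raise ValueError("need at least two samples to track enrichment")
    labels = [s.label for s in samples]
    if len(set(labels)) != len(labels):
        raise ValueError(f"duplicate round labels: {labels}")
    for s in samples:
        if not s.counts:
            raise ValueError(f"sample {s.label!r} is empty")

    freq_maps = [s.frequencies_pct() for s in samples]
    union: set[ClonotypeKey] = set()
    for m in freq_maps:
        union.update(m)

    records = []
    for key in sorted(
        union,
        key=lambda k: (k.v_gene, k.j_gene, k.junction_aa,
                       k.v_3p_deletion, k.j_5p_deletion, k.ndn_length),
    ):
        traj: dict[str, float | None] = {
            lab: m.get(key) for lab, m in zip(labels, freq_maps)
        }
        first, last = traj[labels[0]], traj[labels[-1]]
        if first is None and pseudo_floor and last is not None:
            first = 100.0 / samples[0].total_identified
        fold = (
            fold_enrichment(first, last)
            if first is not None and last is not None
            else None
        )
        records.append(
            EnrichmentRecord(
                clonotype=key,
                freq_pct_by_round=traj,
                fold_change=fold,
                status=classify(fold, flat_band),
                tier_final=tier(last) if last is not None else TIERS[0],
            )
        )
    return records


def scatter_table(
    records: list[EnrichmentRecord],
    round_a: str,
    round_b: str,
    pseudo_floor_pct: float | None = None,
) -> pd.DataFrame:
    """Frequency pairs for a before/after scatter (one row per clonotype seen
    in ``round_b``).

    Clonotypes unobserved in ``round_a`` carry ``pseudo_floor_pct`` when
    given, else NA.  The ``above_diagonal`` column marks clonotypes whose
    frequency rose through panning (points above the identity line).
    """
    if not records:
        return pd.DataFrame(columns=["freq_a", "freq_b", "status", "above_diagonal"])
    known = records[0].freq_pct_by_round.keys()
    for r in (round_a, round_b):
        if r not in known:
            raise KeyError(f"unknown round label {r!r}; have {sorted(known)}")
    rows = []
    for rec in records:
        fb = rec.freq_pct_by_round[round_b]
        if fb is None:
            continue
        fa = rec.freq_pct_by_round[round_a]
        if fa is None:
            fa = pseudo_floor_pct
        rows.append(
            {
                "clonotype": rec.clonotype,
                "freq_a": fa,
                "freq_b": fb,
                "status": rec.status,
                "above_diagonal": (fa is not None and fb > fa),
            }
        )
    return pd.DataFrame(rows)


def records_to_frame(records: list[EnrichmentRecord]) -> pd.DataFrame:
    """Flatten records to a TSV-ready table."""
    rows = []
    for rec in records:
        row = {
            "v_gene": rec.clonotype.v_gene,
            "j_gene": rec.clonotype.j_gene,
            "v_3p_deletion": rec.clonotype.v_3p_deletion,
            "j_5p_deletion": rec.clonotype.j_5p_deletion,
            "ndn_length": rec.clonotype.ndn_length,
            "junction_aa": rec.clonotype.junction_aa,
        }
        for lab, f in rec.freq_pct_by_round.items():
            row[f"freq_pct_{lab}"] = f
        row["fold_change"] = rec.fold_change
        row["fold_display"] = (
            format_fold(rec.fold_change) if rec.fold_change is not None else "NA"
        )
        row["status"] = rec.status
        row["tier_final"] = rec.tier_final
        rows.append(row)
    return pd.DataFrame(rows)
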