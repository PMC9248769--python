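"""Depth-normalized repertoire summary statistics.

Diversity is reported as the effective number of species (Hill number of
order 1), exp of the natural-log Shannon entropy of the clonotype frequency
distribution: the number of equally abundant clonotypes that would give the
observed average proportional abundance.  Evenness is Pielou's H / ln(S).
Because these quantities depend on sequencing depth, they are computed on a
fixed-size random subsample (default 50,000 reads, drawn without
replacement).
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass

import numpy as np

from .clonotyping import ClonotypeKey, RepertoireSample

__all__ = [
    "DiversityReport",
    "Spectratype",
    "subsample",
    "shannon_entropy",
    "diversity",
    "evenness",
    "dominance",
    "spectratype",
    "unique_cdrh3_ratio",
    "total_unique_ratio",
    "diversity_report",
]

log = logging.getLogger(__name__)


@dataclass
class DiversityReport:
    """Per-sample summary at a fixed subsampling depth."""

    label: str
    depth: int
    seed: int
    n_clonotypes_obs: int
    shannon_H: float
    diversity_D: float
    evenness_E: float | None
    dominance_pct: float
    n_cdrh3_total: int
    n_cdrh3_unique: int
    unique_ratio: int
    dominance_full_pct: float | None = None


@dataclass
class Spectratype:
    """Read-weighted CDRH3 amino-acid length distribution (percent)."""

    label: str
    percent_by_length: dict[int, float]
    mean_length: float


def _counts(sample: RepertoireSample) -> np.ndarray:
    if not sample.counts:
        raise ValueError(f"sample {sample.label!r} is empty")
    return np.array(list(sample.counts.values()), dtype=np.int64)


def subsample(sample: RepertoireSample, depth: int = 50_000, seed: int = 0) -> RepertoireSample:
    """Random subsample of ``depth`` reads drawn without replacement.

    Returns the sample unchanged (with a logged notice) when it already holds
    ``depth`` reads or fewer.
    """
    if depth <= 0:
        raise ValueError("depth must be >= 1")
    total = sample.n_reads
    if depth >= total:
        if depth > total:
            log.info(
                "sample %s has %d reads <= requested depth %d; returned unchanged",
                sample.label, total, depth,
            )
        return sample
    keys = sorted(
        sample.counts,
        key=lambda k: (k.v_gene, k.j_gene, k.junction_aa,
                       k.v_3p_deletion, k.j_5p_deletion, k.ndn_length),
    )
    colors = np.array([sample.counts[k] for k in keys], dtype=np.int64)
    rng = np.random.default_rng(seed)
    drawn = rng.multivariate_hypergeometric(colors, depth, method="marginals")
    return RepertoireSample(
        label=sample.label,
        counts=Counter({keys[i]: int(c) for i, c in enumerate(drawn) if c > 0}),
        total_identified=depth,
    )


def shannon_entropy(freqs) -> float:
    """Shannon entropy H = -sum p_i ln p_i, in nats."""
    p = np.asarray(list(freqs), dtype=float)
    if p.size == 0:
        raise ValueError("empty frequency vector")
    if np.any(p <= 0):
        raise ValueError("all proportions must be > 0")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError(f"proportions sum to {p.sum():.12f}, not 1")
    return float(-(p * np.log(p)).sum())


def diversity(sample: RepertoireSample) -> float:
    """Effective number of clonotypes D = exp(H); D = S for a uniform sample."""
    c = _counts(sample)
    return float(np.exp(shannon_entropy(c / c.sum())))


def evenness(sample: RepertoireSample) -> float | None:
    """Pielou evenness H / ln(S_obs); None (undefined 0/0) for S_obs = 1."""
    c = _counts(sample)
    if c.size == 1:
        return None
    return shannon_entropy(c / c.sum()) / np.log(c.size)


def dominance(sample: RepertoireSample) -> float:
    """Percentage of reads carried by the most frequent clonotype."""
    c = _counts(sample)
    return float(100.0 * c.max() / c.sum())


def spectratype(sample: RepertoireSample, label: str | None = None) -> Spectratype:
    """Read-weighted percent of each CDRH3 aa length (junction length - 2)."""
    c = _counts(sample)  # raises on empty
    total = int(c.sum())
    by_len: Counter[int] = Counter()
    for key, count in sample.counts.items():
        by_len[len(key.junction_aa) - 2] += count
    percents = {
        length: 100.0 * n / total for length, n in sorted(by_len.items())
    }
    mean_length = sum(length * n for length, n in by_len.items()) / total
    return Spectratype(
        label=label or sample.label,
        percent_by_length=percents,
        mean_length=mean_length,
    )


def total_unique_ratio(total: int, unique: int) -> int:
    """total/unique rounded half away from zero (the printed '1 of N' form)."""
    if unique <= 0:
        raise ValueError("unique count must be >= 1")
    q = total / unique
    return int(np.floor(q + 0.5))


def unique_cdrh3_ratio(sample: RepertoireSample) -> tuple[int, int, int]:
    """(total reads, distinct CDRH3 aa strings, rounded total/unique ratio)."""
    c = _counts(sample)
    total = int(c.sum())
    unique = len({k.cdrh3_aa for k in sample.counts})
    return total, unique, total_unique_ratio(total, unique)


def diversity_report(
    sample: RepertoireSample,
    depth: int = 50_000,
    seed: int = 0,
    dominance_on_full: bool = True,
) -> DiversityReport:
    """All per-sample summary statistics on the depth-normalized subsample.

    Dominance is additionally reported on the full sample (the subsampled
    value is the primary one when ``dominance_on_full`` is False).
    """
    sub = subsample(sample, depth=depth, seed=seed)
    c = _counts(sub)
    H = shannon_entropy(c / c.sum())
    total, unique, ratio = unique_cdrh3_ratio(sub)
    return DiversityReport(
        label=sample.label,
        depth=min(depth, sample.n_reads),
        seed=seed,
        n_clonotypes_obs=int(c.size),
        shannon_H=H,
        diversity_D=float(np.exp(H)),
        evenness_E=evenness(sub),
        dominance_pct=dominance(sample) if dominance_on_full else dominance(sub),
        n_cdrh3_total=total,
        n_cdrh3_unique=unique,
        unique_ratio=ratio,
        dominance_full_pct=dominance(sample),
    )
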