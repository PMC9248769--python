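"""End-to-end orchestration: simulate -> clonotype -> stats -> enrich -> cluster.

One root seed drives every stage through numpy's seed-spawning, so a rerun
with the same configuration is byte-identical; a manifest records the
configuration hash and per-file checksums.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .clonotyping import RepertoireSample, repertoire_from_airr, v_subgroup
from .clustering import ProteinEntry, annotate_and_export, distance_matrix, neighbor_joining
from .enrichment import records_to_frame, track_clonotypes
from .germline import make_germline_set
from .published import (
    ANTIBODY_ENRICHMENT,
    CLONE50_FREQ_LIBRARY_PCT,
    CLONE50_FREQ_ROUND2_PCT,
    ROUND_TOTALS,
    SANGER_N,
    SANGER_VH_UNIQUE,
    VL_IDENTITY_5_VS_16,
)
from .simulate import PanningConfig, simulate_campaign
from .stats import diversity_report, spectratype, total_unique_ratio
from .enrichment import fold_enrichment, format_fold
from .clustering import identity_percent

__all__ = ["RunConfig", "run_pipeline", "published_checks"]

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration for one full pipeline run.

    Either ``airr_inputs`` (ordered round label -> AIRR TSV path) or a
    simulator configuration drives the run.
    """

    out_dir: str
    seed: int = 0
    depth: int = 50_000
    airr_inputs: dict[str, str] = field(default_factory=dict)
    simulator: PanningConfig | None = None
    productive_only: bool = True
    pseudo_floor: bool = False
    dominance_on_full: bool = True
    cluster_top_n: int = 20

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        raw = json.loads(Path(path).read_text())
        sim = raw.pop("simulator", None)
        cfg = cls(**raw)
        if sim is not None:
            cfg.simulator = PanningConfig(**sim)
        return cfg

    def config_hash(self) -> str:
        def default(o):
            if dataclasses.is_dataclass(o):
                return dataclasses.asdict(o)
            raise TypeError
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=default)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _load_samples(cfg: RunConfig) -> list[RepertoireSample]:
    if cfg.airr_inputs:
        samples = []
        for label, path in cfg.airr_inputs.items():
            p = Path(path)
            if not p.exists():
                raise FileNotFoundError(f"stage clonotype: round {label!r}: no such file {p}")
            samples.append(
                repertoire_from_airr(p, label, productive_only=cfg.productive_only)
            )
        return samples
    sim = cfg.simulator or PanningConfig(seed=cfg.seed)
    germline = make_germline_set(20, 4, 4, seed=sim.seed)
    _, samples = simulate_campaign(sim, germline)
    return samples


def run_pipeline(cfg: RunConfig) -> dict:
    """Run every stage and write the report bundle under ``cfg.out_dir``.

    Emits per-round diversity reports (stats.tsv), spectratypes
    (spectratype.json), the cross-round enrichment table (enrichment.tsv), a
    junction-sequence NJ tree of the most frequent final-round clonotypes
    (clusters.nwk), and a manifest with config hash and file checksums.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    samples = _load_samples(cfg)

    reports = [
        diversity_report(
            s, depth=cfg.depth, seed=cfg.seed, dominance_on_full=cfg.dominance_on_full
        )
        for s in samples
    ]
    stats_df = pd.DataFrame([dataclasses.asdict(r) for r in reports])
    stats_df.to_csv(out / "stats.tsv", sep="\t", index=False)

    spectra = {
        s.label: dataclasses.asdict(spectratype(s)) for s in samples
    }
    (out / "spectratype.json").write_text(json.dumps(spectra, indent=2, sort_keys=True))

    records = track_clonotypes(samples, pseudo_floor=cfg.pseudo_floor)
    records_to_frame(records).to_csv(out / "enrichment.tsv", sep="\t", index=False)

    final = samples[-1]
    top = sorted(final.counts.items(), key=lambda kv: (-kv[1], kv[0].junction_aa))
    entries = []
    seen_seqs: dict[str, int] = {}
    for key, _count in top:
        if len(entries) >= cfg.cluster_top_n:
            break
        seq = key.junction_aa
        seen_seqs[seq] = seen_seqs.get(seq, 0) + 1
        entries.append(
            ProteinEntry(
                id=f"c{len(entries) + 1}",
                chain="VH",
                sequence=seq,
                v_subgroup=v_subgroup(key.v_gene),
            )
        )
    newick = ""
    if len(entries) >= 2:
        tree = neighbor_joining(distance_matrix(entries))
        newick, _report = annotate_and_export(tree, entries)
        (out / "clusters.nwk").write_text(newick + "\n")

    manifest = {
        "package_version": __version__,
        "seed": cfg.seed,
        "config_hash": cfg.config_hash(),
        "rounds": [s.label for s in samples],
        "files": {
            p.name: hashlib.sha256(p.read_bytes()).hexdigest()
            for p in sorted(out.iterdir())
            if p.name != "manifest.json"
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def published_checks() -> pd.DataFrame:
    """Recompute every published desk-scale quantity and compare.

    The inputs are the printed per-antibody frequencies and screen counts
    bundled in :mod:`phagepan.published`; every expected value is recomputed
    by the package's own functions.
    """
    rows = []

    for row in ANTIBODY_ENRICHMENT.itertuples(index=False):
        fold = fold_enrichment(row.freq_library_pct, row.freq_round2_pct)
        computed = format_fold(fold)
        expected = f"{row.printed_fold:,}"
        rows.append(
            {
                "check": f"fold enrichment antibody #{row.antibody}",
                "expected": expected,
                "computed": computed,
                "ok": computed == expected,
            }
        )

    for label, expected_ratio in (("library", 10), ("round2", 43)):
        t = ROUND_TOTALS[label]
        ratio = total_unique_ratio(t["cdrh3_total"], t["cdrh3_unique"])
        rows.append(
            {
                "check": f"total/unique CDRH3 ratio ({label})",
                "expected": str(expected_ratio),
                "computed": str(ratio),
                "ok": ratio == expected_ratio,
            }
        )

    depletion = 1.0 / fold_enrichment(CLONE50_FREQ_LIBRARY_PCT, CLONE50_FREQ_ROUND2_PCT)
    rows.append(
        {
            "check": "clone #50 fold depletion",
            "expected": "10",
            "computed": f"{depletion:g}",
            "ok": abs(depletion - 10.0) < 1e-9,
        }
    )

    unique_pct = round(100.0 * SANGER_VH_UNIQUE / SANGER_N, 1)
    rows.append(
        {
            "check": "unique VH fraction of Sanger screen",
            "expected": "68.2",
            "computed": f"{unique_pct}",
            "ok": unique_pct == 68.2,
        }
    )

    vl_pct = round(identity_percent(*VL_IDENTITY_5_VS_16), 1)
    rows.append(
        {
            "check": "VL identity #5 vs #16",
            "expected": "51.8",
            "computed": f"{vl_pct}",
            "ok": vl_pct == 51.8,
        }
    )
    return pd.DataFrame(rows)
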