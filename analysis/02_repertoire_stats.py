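#!/usr/bin/env python
"""Depth-normalized diversity, evenness, dominance and CDRH3 spectratypes
per panning stage.

Reads the AIRR TSVs written by 01_simulate_panning.py, collapses each round
into clonotypes and reports the round-summary statistics table at a fixed
50,000-read subsample, mirroring how an immune library's collapse through
panning is quantified.  Writes results/stats.tsv and
results/spectratype.json.
"""

import dataclasses
import json
from pathlib import Path

import pandas as pd

from phagepan.clonotyping import repertoire_from_airr
from phagepan.stats import diversity_report, spectratype

ROOT = Path(__file__).resolve().parent.parent / "results"
SEED = 42
ROUNDS = ["library", "round1", "round2"]


def main() -> None:
    samples = [
        repertoire_from_airr(ROOT / "simulation" / f"{label}.airr.tsv", label)
        for label in ROUNDS
    ]
    reports = [diversity_report(s, depth=50_000, seed=SEED) for s in samples]
    df = pd.DataFrame([dataclasses.asdict(r) for r in reports])
    df.to_csv(ROOT / "stats.tsv", sep="\t", index=False)
    print(df[["label", "n_clonotypes_obs", "diversity_D", "evenness_E",
              "dominance_pct", "unique_ratio"]].to_string(index=False))

    spectra = {s.label: dataclasses.asdict(spectratype(s)) for s in samples}
    (ROOT / "spectratype.json").write_text(json.dumps(spectra, indent=2))
    means = {lab: round(sp["mean_length"], 2) for lab, sp in spectra.items()}
    print(f"mean CDRH3 length per round: {means}")
    print("diversity and evenness collapse through the two selection rounds; "
          "the library's bell-shaped CDRH3 length profile narrows as "
          "dominant clones take over.")


if __name__ == "__main__":
    main()
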