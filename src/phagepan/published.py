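"""Published study values used as analysis inputs.

The raw sequencing data behind the study are not deposited, but its printed
summary tables are: per-antibody frequencies before/after panning, the
round-level read totals, and the Sanger-screen counts.  These constants are
inputs to the reproduction checks (``pipeline.paper_checks`` and the
acceptance script) — the package recomputes every derived quantity (fold
enrichment, total/unique ratios, unique fractions, percent identities) from
them at run time.
"""

from __future__ import annotations

import pandas as pd

#: The nine myeloma-binding antibodies: frequency (%) in the immune library
#: and after the second panning round, with the fold enrichment as printed.
ANTIBODY_ENRICHMENT = pd.DataFrame(
    [
        # id, v_gene, cdrh3, freq library %, freq after 2nd panning %, printed fold
        ("25", "IGHV1S81", "ARKRYYAMDY", 0.000458, 7.069747, 15_436),
        ("13", "IGHV1S29", "ARGLRGAMDY", 0.000171, 1.976183, 11_557),
        ("32", "IGHV14-3", "ARRLRLDY", 0.002420, 5.528296, 2_284),
        ("16", "IGHV14-3", "ARRLRLDY", 0.003009, 6.514579, 2_165),
        ("19", "IGHV1S29", "ARRDRLDY", 0.000016, 0.020615, 1_288),
        ("9", "IGHV14-3", "ARRRY", 0.000287, 0.109105, 380),
        ("5(CD38)", "IGHV5-9-3", "ARQKNGYVDY", 0.045049, 9.558421, 212),
        ("23(ICAM-1)", "IGHV2-6-4", "ARYGNYVPFDY", 0.002436, 0.493202, 202),
        ("30", "IGHV1-7", "ARHYGNLFDY", 0.029513, 1.219803, 41),
    ],
    columns=[
        "antibody",
        "v_gene",
        "cdrh3",
        "freq_library_pct",
        "freq_round2_pct",
        "printed_fold",
    ],
)

#: Round-level totals: CDRH3 aa sequence reads and distinct CDRH3 aa strings.
ROUND_TOTALS = {
    "library": {"cdrh3_total": 12_000_000, "cdrh3_unique": 1_200_000},
    "round1": {"cdrh3_total": 240_000, "cdrh3_unique": 24_167},
    "round2": {"cdrh3_total": 820_000, "cdrh3_unique": 18_926},
}

#: Clone #50: fourth most frequent clonotype in the library, depleted by the
#: leukocyte/selection scheme.
CLONE50_FREQ_LIBRARY_PCT = 0.9
CLONE50_FREQ_ROUND2_PCT = 0.09

#: Sanger screen of 66 randomly picked phage antibodies after round 2.
SANGER_N = 66
SANGER_VH_UNIQUE = 45
SANGER_VL_UNIQUE = 46

#: Percent-identity anchor pairs (matches, alignment columns).
VH_IDENTITY_5_VS_16 = (21, 117)
VL_IDENTITY_5_VS_16 = (58, 112)
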