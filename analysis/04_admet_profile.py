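#!/usr/bin/env python
"""Stage 4 — ADMET rule profiling of the ten candidate compounds.

Recomputes the Lipinski (VRF) and Jorgensen (VRT) violation counts from
the bundled descriptor table, checks them against the published columns,
and evaluates the blood–brain-barrier range for every compound.  Writes
results/04_admet_profile/.
"""

import json
from pathlib import Path

import pandas as pd

from eiipscreen.admet import druglikeness_report
from eiipscreen.datasets import admet_candidate_rows, admet_candidates

OUT = Path("results/04_admet_profile")
OUT.mkdir(parents=True, exist_ok=True)

rows = admet_candidate_rows()
reports, max_violations = druglikeness_report(rows)
published = admet_candidates()

df = pd.DataFrame(
    [
        {"id": r.id, "vrf": r.vrf, "vrt": r.vrt,
         "vrf_reasons": ";".join(r.vrf_reasons) or "-",
         "vrt_reasons": ";".join(r.vrt_reasons) or "-",
         "bbb_in_range": r.bbb_in_range}
        for r in reports
    ]
)
df.to_csv(OUT / "rule_report.tsv", sep="\t", index=False)

vrf_match = df["vrf"].tolist() == published["VRF"].tolist()
vrt_match = df["vrt"].tolist() == published["VRT"].tolist()
print(df.to_string(index=False))
print(f"recomputed VRF column matches published: {vrf_match}")
print(f"recomputed VRT column matches published: {vrt_match}")
print(f"all {len(reports)} compounds cause no more than {max_violations} "
      f"violation(s) of either rule set; "
      f"{int(df['bbb_in_range'].sum())}/{len(df)} inside the BBB range")

(OUT / "summary.json").write_text(json.dumps({
    "max_violations": max_violations,
    "vrf_match": vrf_match,
    "vrt_match": vrt_match,
    "n_bbb_in_range": int(df["bbb_in_range"].sum()),
}, indent=2))
print(f"wrote {OUT}/rule_report.tsv and summary.json")
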