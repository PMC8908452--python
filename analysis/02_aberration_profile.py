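#!/usr/bin/env python
"""Aberration profile of the cohort: frequency tables and clonality calls.

Reads results/cohort/karyotypes.tsv, tallies chromosomal variants and
alterations per individual, builds the carrier-frequency comparison (with
two-sided Fisher exact p per category), the per-pair event table, the
CCA/NCCA clonality breakdown and the recurrently altered regions, and writes
them under results/.
"""

import json
from pathlib import Path

import pandas as pd

from cytocin.aberrations import (
    TALLY_CATEGORIES,
    call_clonality,
    carriers_table,
    recurrent_regions,
    tally_individual,
)
from cytocin.iscn import read_karyotypes

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    records = read_karyotypes(ROOT / "cohort" / "karyotypes.tsv")
    meta = pd.read_csv(ROOT / "cohort" / "metadata.tsv", sep="\t").set_index(
        "individual_id"
    )
    by_ind: dict[str, list] = {}
    for r in records:
        by_ind.setdefault(r.individual_id, []).append(r)

    group_totals = {"exposed": 0, "unexposed": 0}
    for ind, recs in by_ind.items():
        group_totals[meta.loc[ind, "group"]] += len(recs)

    tallies = {"exposed": [], "unexposed": []}
    for ind, recs in sorted(by_ind.items()):
        g = meta.loc[ind, "group"]
        sex = "XX" if meta.loc[ind, "sex"] == "F" else "XY"
        tallies[g].append(
            tally_individual(recs, group_totals[g], group=g, constitutional_sex=sex)
        )

    tally_df = pd.DataFrame([t.__dict__ for t in tallies["exposed"] + tallies["unexposed"]])
    tally_df.to_csv(ROOT / "individual_tallies.tsv", sep="\t", index=False)

    rows = []
    for cat in TALLY_CATEGORIES:
        rows.append(carriers_table(tallies["exposed"], tallies["unexposed"], cat).__dict__)
    carrier_df = pd.DataFrame(rows)
    carrier_df.to_csv(ROOT / "carrier_table.tsv", sep="\t", index=False)

    clonality = {}
    for g in ("exposed", "unexposed"):
        cca = ncca = 0
        for t in tallies[g]:
            recs = by_ind[t.individual_id]
            sex = "XX" if meta.loc[t.individual_id, "sex"] == "F" else "XY"
            for c in call_clonality(recs, constitutional_sex=sex):
                cca += c.call == "CCA"
                ncca += c.call == "NCCA"
        clonality[g] = {"CCA": cca, "NCCA": ncca}
    (ROOT / "clonality.json").write_text(json.dumps(clonality, indent=2) + "\n")

    recur = recurrent_regions(records, min_individuals=2)
    recur.to_csv(ROOT / "recurrent_regions.tsv", sep="\t", index=False)

    te = sum(t.total_events for t in tallies["exposed"])
    tu = sum(t.total_events for t in tallies["unexposed"])
    print(f"group totals: exposed {te} events / {group_totals['exposed']} metaphases, "
          f"unexposed {tu} / {group_totals['unexposed']}")
    sig = carrier_df[carrier_df.p_two_sided < 0.05].category.tolist()
    print(f"carrier categories with p < 0.05: {sig}")
    print(f"clonality: {clonality}")
    print(f"recurrently altered bands (>=2 individuals): {len(recur)}; "
          f"top: {recur.head(3).to_dict('records')}")


if __name__ == "__main__":
    main()
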