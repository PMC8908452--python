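#!/usr/bin/env python
"""Clonal heterogeneity: Shannon diversity, true diversity and CH classes.

Computes per-individual SDI and TD from full 6-probe clone signatures (plus
the per-chromosome marginal TD, the scale on which the CH classes and the
group ratio are interpreted), compares groups, and writes results/diversity.tsv.
"""

import json
from pathlib import Path

import pandas as pd

from cytocin.diversity import chromosome_mean_td, classify_ch, diversity_of
from cytocin.fish import read_fish_counts
from cytocin.stats import compare_groups, kruskal_wallis

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    matrices = read_fish_counts(ROOT / "cohort" / "fish_counts.tsv")
    meta = pd.read_csv(ROOT / "cohort" / "metadata.tsv", sep="\t").set_index(
        "individual_id"
    )
    rows = []
    for m in matrices:
        res = diversity_of(m)  # full 6-tuple signatures
        ctd = chromosome_mean_td(m)
        rows.append({
            "individual_id": m.individual_id,
            "group": meta.loc[m.individual_id, "group"],
            "sdi": res.sdi, "td": res.td, "n_clones": res.n_clones,
            "ch_class_signature": res.ch_class,
            "chromosome_mean_td": ctd,
            "ch_class_marginal": classify_ch(max(ctd, 1.0)),
        })
    df = pd.DataFrame(rows)
    df.to_csv(ROOT / "diversity.tsv", sep="\t", index=False)

    comparisons = {}
    for var in ("sdi", "td", "chromosome_mean_td"):
        r = compare_groups(df.loc[df.group == "exposed", var],
                           df.loc[df.group == "unexposed", var])
        comparisons[var] = r.__dict__

    # per-chromosome TD differences within each group
    per_chrom = {}
    from cytocin.diversity import diversity_of as div
    for g in ("exposed", "unexposed"):
        ids = df.loc[df.group == g, "individual_id"]
        mats = {m.individual_id: m for m in matrices}
        groups = []
        for probe in mats[ids.iloc[0]].probes:
            groups.append([div(mats[i], level=probe).td for i in ids])
        per_chrom[g] = kruskal_wallis(groups).__dict__

    ratio = (df.loc[df.group == "exposed", "chromosome_mean_td"].mean()
             / df.loc[df.group == "unexposed", "chromosome_mean_td"].mean())
    out = {"group_comparisons": comparisons, "per_chromosome_td_kw": per_chrom,
           "marginal_td_ratio_exposed_over_unexposed": ratio}
    (ROOT / "diversity_summary.json").write_text(json.dumps(out, indent=2) + "\n")

    ch_counts = df.groupby("group").ch_class_marginal.value_counts().to_dict()
    print(f"CH classes (marginal TD): {ch_counts}")
    print(f"marginal TD ratio exposed/unexposed: {ratio:.2f}")
    for var, r in comparisons.items():
        print(f"{var}: {r['test_name']} p = {r['p_two_sided']:.3g}")


if __name__ == "__main__":
    main()
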