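"""Pipeline orchestration and rendering of the cohort-style output tables.

``run_pipeline`` ties the modules together: obtain a cohort (from input TSVs
or the synthetic generator), build the carrier-frequency and per-pair event
tables, score CIN and clonal diversity, run the group comparisons and the
correlation matrices, and write everything plus a reproducibility manifest to
an output directory.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .aberrations import (
    TALLY_CATEGORIES,
    IndividualTally,
    call_clonality,
    carriers_table,
    recurrent_regions,
    tally_individual,
)
from .diversity import chromosome_mean_td, diversity_of
from .fish import chromosome_stability, cin_individual, read_fish_counts
from .iscn import read_karyotypes
from .simulate import (
    CohortConfig,
    default_karyotype_model,
    simulate_cohort,
    simulate_karyotypes,
)
from .stats import TwoByTwo, compare_groups, correlation_matrix, fisher_exact

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "render_carrier_table",
           "render_pair_table"]

#: display names for the carrier table rows
CATEGORY_LABELS = {
    "monosomies": "Monosomies",
    "trisomies": "Trisomies",
    "scas": "SCAs",
    "chtb_chrb": "chtb/chrb",
    "fra_other": "fra",
    "fra_9q12": "fra(9)(q12)",
    "cv_1qh": "1qh+",
    "cv_9qh": "9qh+",
    "cv_inv9": "inv(9)",
    "cv_16qh": "16qh+",
}


@dataclass
class RunConfig:
    """Inputs, thresholds and output location for one pipeline run."""

    karyotypes: str | None = None  # TSV; simulated when absent
    fish: str | None = None  # TSV; simulated when absent
    metadata: str | None = None  # TSV with individual_id, group, age, sex, ...
    out_dir: str = "results"
    seed: int = 0
    n_per_group: int = 34
    cin_high: float = 25.0
    ch_low: float = 1.5
    ch_high: float = 2.0
    alpha: float = 0.05
    format: str = "tsv"  # tsv | md

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        if min(self.cin_high, self.ch_low, self.ch_high) <= 0:
            raise ValueError("thresholds must be positive")


@dataclass
class PipelineResult:
    carrier_table: pd.DataFrame
    pair_table: pd.DataFrame
    cin_table: pd.DataFrame
    diversity_table: pd.DataFrame
    recurrent: pd.DataFrame
    correlations: dict[str, pd.DataFrame]
    clonality_summary: dict
    tests: list[dict]
    manifest: dict


def _paired_fisher(e_events: int, e_total: int, u_events: int, u_total: int) -> float:
    """Per-pair Fisher on [events, remaining metaphase-events] vs group totals.

    The closest reading of per-pair event comparisons against group totals;
    labelled as such in the output.
    """
    return fisher_exact(
        TwoByTwo(e_events, e_total - e_events, u_events, u_total - u_events)
    ).p_two_sided


def render_carrier_table(df: pd.DataFrame) -> str:
    """Markdown rendering of the carrier table ('Exposed n (%) Unexposed n (%) p')."""
    lines = ["| CVs and CAs | Exposed n (%) | Unexposed n (%) | p |",
             "|---|---|---|---|"]
    for _, row in df.iterrows():
        def fmt(n, pct):
            pct_s = "0" if n == 0 else f"{pct:g}"
            return f"{n} ({pct_s})"
        lines.append(
            f"| {row['category_label']} | {fmt(row['exposed_carriers'], row['pct_exposed'])} "
            f"| {fmt(row['unexposed_carriers'], row['pct_unexposed'])} "
            f"| {row['p_two_sided']:.4g} |"
        )
    return "\n".join(lines)


def render_pair_table(df: pd.DataFrame) -> str:
    """Markdown rendering of the per-pair event table with a grand-totals row."""
    lines = ["| No | Exposed n | Exposed % | Unexposed n | Unexposed % | p |",
             "|---|---|---|---|---|---|"]
    for _, row in df.iterrows():
        lines.append(
            f"| {row['pair']} | {row['exposed_events']} | {row['exposed_pct']:.2f} "
            f"| {row['unexposed_events']} | {row['unexposed_pct']:.2f} "
            f"| {row['p_two_sided']:.2g} |"
        )
    lines.append(
        f"| Total | {df['exposed_events'].sum()} |  | {df['unexposed_events'].sum()} |  |  |"
    )
    return "\n".join(lines)


def _load_or_simulate(config: RunConfig):
    """Return (fish matrices dict, metadata df, karyotype records, sexes)."""
    if config.fish is not None:
        matrices = {m.individual_id: m for m in read_fish_counts(config.fish)}
        if config.metadata is None:
            raise ValueError("metadata TSV is required when fish counts are supplied")
        meta = pd.read_csv(config.metadata, sep="\t")
        required = {"individual_id", "group", "age", "sex", "exposure_months"}
        missing = required - set(meta.columns)
        if missing:
            raise ValueError(f"metadata missing columns: {sorted(missing)}")
    else:
        bundle = simulate_cohort(
            CohortConfig(n_per_group=config.n_per_group), seed=config.seed
        )
        matrices, meta = bundle.fish, bundle.metadata

    if config.karyotypes is not None:
        records = read_karyotypes(config.karyotypes)
        sexes = {}
    else:
        sexes = {}
        records = []
        for group, prefix, offset in (("exposed", "E", 0), ("unexposed", "UE", 1)):
            # bundle metadata rows are already in id order (E1..En, UE1..UEn)
            sub = meta[meta.group == group]
            csex = [
                "XY" if str(s).upper() in ("M", "XY") else "XX" for s in sub["sex"]
            ]
            sim = simulate_karyotypes(
                default_karyotype_model(group),
                n_individuals=config.n_per_group,
                seed=np.random.default_rng([config.seed, offset]),
                id_prefix=prefix,
                constitutional_sexes=csex,
            )
            records.extend(sim.records)
            sexes.update(sim.constitutional_sex)
    return matrices, meta, records, sexes


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Run the full analysis and write tables, reports and a manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tests: list[dict] = []

    matrices, meta, records, sexes = _load_or_simulate(config)
    meta = meta.set_index("individual_id", drop=False)
    groups_of = meta["group"].to_dict()

    # ---- aberration profile --------------------------------------------
    by_ind: dict[str, list] = {}
    for r in records:
        by_ind.setdefault(r.individual_id, []).append(r)

    def sex_of(ind: str) -> str:
        if ind in sexes:
            return sexes[ind]
        if ind in meta.index and str(meta.loc[ind, "sex"]).upper() in ("F", "XX"):
            return "XX"
        return "XY"

    group_totals = {"exposed": 0, "unexposed": 0}
    ind_group = {}
    for ind, recs in by_ind.items():
        g = groups_of.get(ind) or ("exposed" if ind.startswith("E") else "unexposed")
        ind_group[ind] = g
        group_totals[g] += len(recs)

    tallies: dict[str, list[IndividualTally]] = {"exposed": [], "unexposed": []}
    for ind, recs in by_ind.items():
        g = ind_group[ind]
        tallies[g].append(
            tally_individual(recs, group_totals[g], group=g, constitutional_sex=sex_of(ind))
        )
    for g in tallies:
        tallies[g].sort(key=lambda t: t.individual_id)

    carrier_rows = []
    for cat in TALLY_CATEGORIES:
        row = carriers_table(tallies["exposed"], tallies["unexposed"], cat)
        d = asdict(row)
        d["category_label"] = CATEGORY_LABELS[cat]
        carrier_rows.append(d)
        tests.append({"test": "fisher_exact", "context": f"carriers:{cat}",
                      "p": row.p_two_sided})
    carrier_df = pd.DataFrame(carrier_rows)

    n_pairs = min(len(tallies["exposed"]), len(tallies["unexposed"]))
    pair_rows = []
    for i in range(n_pairs):
        te, tu = tallies["exposed"][i], tallies["unexposed"][i]
        p = _paired_fisher(
            te.total_events, group_totals["exposed"],
            tu.total_events, group_totals["unexposed"],
        )
        pair_rows.append(
            {
                "pair": i + 1,
                "exposed_id": te.individual_id,
                "exposed_events": te.total_events,
                "exposed_pct": te.pct_of_group_metaphases,
                "unexposed_id": tu.individual_id,
                "unexposed_events": tu.total_events,
                "unexposed_pct": tu.pct_of_group_metaphases,
                "p_two_sided": p,
            }
        )
    pair_df = pd.DataFrame(pair_rows)

    clonality_summary: dict[str, dict] = {}
    for g in ("exposed", "unexposed"):
        cca = ncca = 0
        for ind, recs in by_ind.items():
            if ind_group[ind] != g:
                continue
            for call in call_clonality(recs, constitutional_sex=sex_of(ind)):
                if call.call == "CCA":
                    cca += 1
                else:
                    ncca += 1
        clonality_summary[g] = {"CCA": cca, "NCCA": ncca,
                                "metaphases": group_totals[g]}

    recurrent = recurrent_regions(records, min_individuals=2)

    # ---- FISH CIN -------------------------------------------------------
    cin_rows = []
    profiles = {"exposed": [], "unexposed": []}
    for ind in sorted(matrices):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            prof = cin_individual(matrices[ind])
        g = groups_of.get(ind, "exposed" if ind.startswith("E") else "unexposed")
        profiles[g].append(prof)
        row = prof.as_dict()
        row["group"] = g
        cin_rows.append(row)
    cin_df = pd.DataFrame(cin_rows)

    cmp_cin = compare_groups(
        cin_df.loc[cin_df.group == "exposed", "mean_cin"],
        cin_df.loc[cin_df.group == "unexposed", "mean_cin"],
    )
    tests.append({"test": cmp_cin.test_name, "context": "cin:exposed_vs_unexposed",
                  "p": cmp_cin.p_two_sided, "gate_trace": cmp_cin.gate_trace})
    stability = {}
    for g in ("exposed", "unexposed"):
        ranking, kw = chromosome_stability(profiles[g])
        stability[g] = {"ranking_most_stable_first": ranking,
                        "kruskal_wallis_p": kw.p_two_sided}
        tests.append({"test": kw.test_name, "context": f"chromosome_stability:{g}",
                      "p": kw.p_two_sided})

    # ---- clonal diversity ----------------------------------------------
    div_rows = []
    for ind in sorted(matrices):
        res = diversity_of(matrices[ind], level="individual")
        g = groups_of.get(ind, "exposed" if ind.startswith("E") else "unexposed")
        div_rows.append(
            {
                "individual_id": ind,
                "group": g,
                "sdi": res.sdi,
                "td": res.td,
                "ch_class": res.ch_class,
                "n_clones": res.n_clones,
                "chromosome_mean_td": chromosome_mean_td(matrices[ind]),
            }
        )
    div_df = pd.DataFrame(div_rows)
    for var in ("sdi", "td"):
        cmp_r = compare_groups(
            div_df.loc[div_df.group == "exposed", var],
            div_df.loc[div_df.group == "unexposed", var],
        )
        tests.append({"test": cmp_r.test_name, "context": f"{var}:exposed_vs_unexposed",
                      "p": cmp_r.p_two_sided, "gate_trace": cmp_r.gate_trace})

    # ---- correlations ---------------------------------------------------
    correlations = {}
    merged = cin_df[["individual_id", "group", "mean_cin"]].merge(
        div_df[["individual_id", "sdi", "td"]], on="individual_id"
    ).merge(
        meta[["individual_id", "age", "sex", "exposure_months"]].reset_index(drop=True),
        on="individual_id",
    )
    merged["sex"] = (merged["sex"].astype(str).str.upper()
                     .map({"M": 1, "XY": 1, "F": 0, "XX": 0}))
    for g in ("exposed", "unexposed"):
        cols = ["mean_cin", "td", "sdi", "age", "sex"]
        if g == "exposed":
            cols.append("exposure_months")
        sub = merged.loc[merged.group == g, cols]
        correlations[g] = correlation_matrix(sub).r

    # ---- write outputs --------------------------------------------------
    carrier_df.to_csv(out / "carrier_table.tsv", sep="\t", index=False)
    pair_df.to_csv(out / "pair_table.tsv", sep="\t", index=False)
    cin_df.to_csv(out / "cin_profiles.tsv", sep="\t", index=False)
    div_df.to_csv(out / "diversity.tsv", sep="\t", index=False)
    recurrent.to_csv(out / "recurrent_regions.tsv", sep="\t", index=False)
    for g, mat in correlations.items():
        mat.to_csv(out / f"correlation_{g}.tsv", sep="\t")
    if config.format == "md":
        (out / "carrier_table.md").write_text(render_carrier_table(carrier_df) + "\n")
        (out / "pair_table.md").write_text(render_pair_table(pair_df) + "\n")

    manifest = {
        "version": __version__,
        "config": asdict(config),
        "seed": config.seed,
        "group_metaphase_totals": group_totals,
        "clonality_summary": clonality_summary,
        "chromosome_stability": stability,
        "n_statistical_tests": len(tests),
        "tests": tests,
        "notes": [
            "pair_table p-values: Fisher on [events_i, group_total - events_i] per pair",
            "no multiple-testing correction applied",
        ],
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    (out / "clonality.json").write_text(
        json.dumps(clonality_summary, indent=2, sort_keys=True) + "\n"
    )

    return PipelineResult(
        carrier_table=carrier_df,
        pair_table=pair_df,
        cin_table=cin_df,
        diversity_table=div_df,
        recurrent=recurrent,
        correlations=correlations,
        clonality_summary=clonality_summary,
        tests=tests,
        manifest=manifest,
    )
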