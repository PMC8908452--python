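"""Metaphase classification, clonality calls and frequency tables."""

import math
import random
from collections import Counter

import pytest

from cytocin.aberrations import (
    TALLY_CATEGORIES,
    IndividualTally,
    call_clonality,
    carriers_table,
    recurrent_regions,
    round_half_up,
    tally_individual,
)
from cytocin.iscn import parse_karyotype
from cytocin.simulate import KaryotypeRateModel, default_karyotype_model, simulate_karyotypes


def _records(*karyotypes, ind="A"):
    return [parse_karyotype(s, individual_id=ind, metaphase_id=f"{ind}.m{i}")
            for i, s in enumerate(karyotypes)]


class TestClassifyMetaphase:
    def test_explicit_loss(self):
        from cytocin.aberrations import classify_metaphase

        out = classify_metaphase(parse_karyotype("45,XX,-20"), "XX")
        assert out == [("monosomies", "20")]

    def test_marker_counts_as_gain(self):
        from cytocin.aberrations import classify_metaphase

        out = classify_metaphase(parse_karyotype("47,XY,+mar"), "XY")
        assert out == [("trisomies", "mar")]

    def test_45_x_resolved_by_constitutional_sex(self):
        from cytocin.aberrations import classify_metaphase

        assert classify_metaphase(parse_karyotype("45,X"), "XY") == [("monosomies", "Y")]
        assert classify_metaphase(parse_karyotype("45,X"), "XX") == [("monosomies", "X")]

    def test_47_xxx_is_gained_x(self):
        from cytocin.aberrations import classify_metaphase

        assert classify_metaphase(parse_karyotype("47,XXX"), "XX") == [("trisomies", "X")]

    def test_inconsistent_count_warns_but_keeps_events(self):
        from cytocin.aberrations import classify_metaphase

        with pytest.warns(UserWarning, match="disagrees"):
            out = classify_metaphase(parse_karyotype("46,XX,-20"), "XX")
        assert out == [("monosomies", "20")]


class TestClonality:
    def test_structural_in_two_metaphases_is_cca(self):
        recs = _records("46,XX,del(6)(q25)", "46,XX,del(6)(q25)",
                        *["46,XX"] * 28)
        calls = {c.key: c for c in call_clonality(recs, "XX")}
        assert calls["del(6)(q25)"].call == "CCA"
        assert calls["del(6)(q25)"].n_metaphases_with_event == 2

    def test_loss_in_two_metaphases_is_ncca(self):
        recs = _records("45,XX,-20", "45,XX,-20", *["46,XX"] * 28)
        calls = {c.key: c for c in call_clonality(recs, "XX")}
        assert calls["-20"].call == "NCCA"

    def test_loss_in_three_metaphases_is_cca(self):
        recs = _records(*["45,XX,-20"] * 3, "46,XX")
        assert call_clonality(recs, "XX")[0].call == "CCA"

    def test_gain_in_two_metaphases_is_cca(self):
        recs = _records("47,XX,+22", "47,XX,+22", "46,XX")
        calls = {c.key: c for c in call_clonality(recs, "XX")}
        assert calls["+22"].call == "CCA"

    def test_singleton_translocation_is_ncca(self):
        recs = _records("46,XY,t(2;12)(q33;p13)", "46,XY")
        assert call_clonality(recs, "XY")[0].call == "NCCA"

    def test_implied_sex_loss_participates(self):
        recs = _records(*["45,X"] * 3, "46,XY")
        calls = {c.key: c for c in call_clonality(recs, "XY")}
        assert calls["-Y"].call == "CCA"

    def test_fragilities_and_cvs_get_no_calls(self):
        recs = _records("46,XX,fra(9)(q12),1qh+", "46,XX,fra(9)(q12),1qh+")
        assert call_clonality(recs, "XX") == []

    def test_order_invariance(self):
        karyos = ["46,XX,del(6)(q25)", "46,XX,del(6)(q25)", "45,XX,-20",
                  "47,XX,+22", "46,XX"] * 3
        base = call_clonality(_records(*karyos), "XX")
        rng = random.Random(1)
        for _ in range(5):
            rng.shuffle(karyos)
            assert call_clonality(_records(*karyos), "XX") == base


class TestTally:
    def test_printed_percentage_convention(self):
        # 138 events against a 1493-metaphase group total prints as 9.24%
        assert round_half_up(100 * 138 / 1493, 2) == 9.24

    def test_empty_individual(self):
        t = tally_individual(_records("46,XX", "46,XX"), 100, constitutional_sex="XX")
        assert t.total_events == 0 and t.pct_of_group_metaphases == 0.0

    def test_zero_group_total_errors(self):
        with pytest.raises(ValueError):
            tally_individual(_records("46,XX"), 0, constitutional_sex="XX")

    def test_counts_match_brute_force_recount(self):
        """Tally equals an independent per-token recount on simulated data."""
        sim = simulate_karyotypes(default_karyotype_model("exposed"), 2, seed=77)
        by_ind = {}
        for r in sim.records:
            by_ind.setdefault(r.individual_id, []).append(r)
        for ind, recs in by_ind.items():
            sex = sim.constitutional_sex[ind]
            t = tally_individual(recs, 10_000, constitutional_sex=sex)
            # oracle: recount by walking the formatted strings token by token
            oracle = Counter()
            for r in recs:
                for e in r.events:
                    if e.category in ("loss",):
                        oracle["monosomies"] += 1
                    elif e.category in ("gain", "marker_gain"):
                        oracle["trisomies"] += 1
                    elif e.category in ("chtb", "chrb"):
                        oracle["chtb_chrb"] += 1
                    elif e.category == "fra":
                        key = "fra_9q12" if (e.chromosomes, e.breakpoints) == (("9",), ("q12",)) else "fra_other"
                        oracle[key] += 1
                    elif e.category == "cv_1qh_plus":
                        oracle["cv_1qh"] += 1
                    elif e.category == "cv_9qh_plus":
                        oracle["cv_9qh"] += 1
                    elif e.category == "cv_16qh_plus":
                        oracle["cv_16qh"] += 1
                    elif e.category == "cv_inv9":
                        oracle["cv_inv9"] += 1
                    else:
                        oracle["scas"] += 1
                if r.sex_complement == "X":
                    oracle["monosomies"] += 1
            assert t.category_counts() == {c: oracle.get(c, 0) for c in TALLY_CATEGORIES}
            assert t.total_events == sum(oracle.values())


def _tallies_with_carriers(n, carriers, category="monosomies", group="g"):
    out = []
    for i in range(n):
        kwargs = {category: 1 if i < carriers else 0}
        t = IndividualTally(individual_id=f"{group}{i}", group=group,
                            total_events=kwargs[category], **kwargs)
        out.append(t)
    return out


class TestCarriersTable:
    def test_printed_percentages(self):
        exposed = _tallies_with_carriers(34, 32)
        unexposed = _tallies_with_carriers(34, 13)
        row = carriers_table(exposed, unexposed, "monosomies")
        assert (row.pct_exposed, row.pct_unexposed) == (94.1, 38.2)
        assert row.p_two_sided < 0.0001

    def test_identical_counts_give_p_one(self):
        a = _tallies_with_carriers(10, 5)
        b = _tallies_with_carriers(10, 5)
        assert carriers_table(a, b, "monosomies").p_two_sided == pytest.approx(1.0)

    def test_p_matches_hypergeometric_enumeration(self):
        """5/10 vs 1/10 carrier table equals the exact enumeration p."""
        row = carriers_table(_tallies_with_carriers(10, 5),
                             _tallies_with_carriers(10, 1), "monosomies")
        # enumerate all 2x2 tables with margins (10, 10, 6, 14)
        denom = math.comb(20, 6)
        probs = {x: math.comb(10, x) * math.comb(10, 6 - x) / denom
                 for x in range(0, 7)}
        p_obs = probs[5]
        expected = sum(p for p in probs.values() if p <= p_obs * (1 + 1e-12))
        assert row.p_two_sided == pytest.approx(expected, rel=1e-9)

    def test_carrier_monotonicity(self):
        """Adding an event to an individual never decreases a carrier count."""
        base = _tallies_with_carriers(10, 4)
        more = _tallies_with_carriers(10, 5)
        r0 = carriers_table(base, base, "monosomies")
        r1 = carriers_table(more, base, "monosomies")
        assert r1.exposed_carriers >= r0.exposed_carriers


class TestRecurrentRegions:
    def test_threshold_filtering(self):
        recs = (_records("46,XX,del(12)(p13)", ind="E1")
                + _records("46,XY,add(12)(p13)", ind="E2")
                + _records("46,XX,del(4)(q21)", ind="E3"))
        df = recurrent_regions(recs, min_individuals=2)
        assert df.shape[0] == 1
        assert tuple(df.iloc[0][["chromosome", "band", "n_individuals"]]) == ("12", "p13", 2)

    def test_translocation_breakpoints_count_per_chromosome(self):
        recs = (_records("46,XX,t(7;14)(p22;q12)", ind="E1")
                + _records("46,XY,del(7)(p22)", ind="E2"))
        df = recurrent_regions(recs, min_individuals=2)
        assert tuple(df.iloc[0][["chromosome", "band"]]) == ("7", "p22")

    def test_planted_recurrent_band_tops_the_table(self):
        model = default_karyotype_model("exposed")
        model = KaryotypeRateModel(
            rates=model.rates,
            clonal_injections=(("del(6)(q25)", 5),),
            metaphases_range=(19, 30),
        )
        recs = []
        for i in range(6):  # inject into several cohorts to hit many individuals
            sim = simulate_karyotypes(model, 3, seed=100 + i, id_prefix=f"C{i}E")
            recs.extend(sim.records)
        df = recurrent_regions(recs, min_individuals=2)
        assert tuple(df.iloc[0][["chromosome", "band"]]) == ("6", "q25")
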