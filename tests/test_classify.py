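"""Interface classification: confidence scoring, motif scanning, labelling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from modulin.classify import (
    AMINO_ACIDS,
    Inventories,
    MotifClass,
    accepted_pairs,
    classify_edges,
    confidence_scores,
    method_precision,
    motif_probability,
    scan_motifs,
    select_cutoff,
    split_homo_hetero,
    stage_quality,
)
from modulin.network import ProteinRecord

from conftest import build_network


class TestMethodPrecision:
    @pytest.mark.parametrize(
        "preds,gold,expected",
        [
            ({("A", "B"), ("C", "D")}, {("A", "B"), ("C", "D"), ("E", "F")}, 1.0),
            ({("A", "B"), ("C", "D"), ("E", "F"), ("G", "H")},
             {("A", "B"), ("C", "D"), ("E", "F")}, 0.75),
            ({("X", "Y")}, {("A", "B")}, 0.0),
        ],
    )
    def test_precision_values(self, preds, gold, expected):
        assert method_precision(preds, gold).weight == expected

    def test_orientation_insensitive(self):
        w = method_precision({("B", "A")}, {("A", "B")})
        assert w.weight == 1.0

    def test_empty_predictions_warn_and_get_zero(self):
        with pytest.warns(UserWarning):
            assert method_precision(set(), {("A", "B")}).weight == 0.0


class TestConfidenceScores:
    def test_weighted_vote(self):
        scores = confidence_scores(
            {"m1": {("A", "B")}, "m2": {("A", "B"), ("C", "D")}},
            {"m1": 0.5, "m2": 0.25},
        )
        assert scores[("A", "B")] == 0.75
        assert scores[("C", "D")] == 0.25

    def test_unknown_method_is_an_error(self):
        with pytest.raises(KeyError):
            confidence_scores({"mystery": {("A", "B")}}, {})


class TestSelectCutoff:
    def test_perfect_scorer_selects_smallest_maximising_cutoff(self):
        scores = {("A", "B"): 1.0, ("C", "D"): 1.0, ("E", "F"): 0.0}
        scan = select_cutoff(scores, {("A", "B"), ("C", "D")})
        assert scan.f1.max() == 1.0
        assert scan.selected == 0.0  # CS > 0 already separates perfectly

    def test_matches_brute_force_grid_search(self):
        rng = np.random.default_rng(7)
        grid = np.round(np.arange(0, 121) * 0.01, 2)
        for _ in range(30):
            pairs = [(f"D{i}", f"D{i + 1}") for i in range(8)]
            scores = {p: float(rng.choice([0, 0.1, 0.25, 0.5, 0.75, 1.0, 1.2]))
                      for p in pairs}
            gold = {p for p in pairs if rng.random() < 0.4} or {pairs[0]}
            scan = select_cutoff(scores, gold, grid=grid)
            # oracle: exhaustive scan computing F1 from first principles
            best_f1, best_cs0 = -1.0, None
            for cs0 in grid:
                positives = {p for p, s in scores.items() if s > cs0}
                tp = len(positives & gold)
                fp = len(positives - gold)
                fn = len(gold) - tp
                pr = tp / (tp + fp) if tp + fp else 0.0
                rc = tp / (tp + fn) if tp + fn else 0.0
                f1 = 2 * pr * rc / (pr + rc) if pr + rc else 0.0
                if f1 > best_f1:
                    best_f1, best_cs0 = f1, cs0
            assert scan.selected == best_cs0
            assert scan.f1.max() == pytest.approx(best_f1)

    def test_gold_pairs_always_accepted(self):
        scores = {("A", "B"): 0.05}
        catalog = accepted_pairs(scores, {("G", "H")}, cs0=0.5)
        assert ("G", "H") in catalog and ("A", "B") not in catalog


class TestScanMotifs:
    def test_no_match_gives_empty(self):
        p = ProteinRecord(id="P", sequence="AAAAAAA")
        cls = MotifClass("LIG_1", "LIG", "WWW", ("SH3",))
        assert scan_motifs(p, [cls]) == []

    def test_leftmost_nonoverlapping_scan(self):
        p = ProteinRecord(id="P", sequence="AAPAPAA")
        cls = MotifClass("LIG_1", "LIG", "P.P", ("SH3",))
        (hit,) = scan_motifs(p, [cls])
        assert (hit.start, hit.end, hit.matched) == (3, 5, "PAP")

    def test_hits_overlapping_domains_are_removed(self):
        seq = "AAPAPAAAAAPAPAA"
        inside = ProteinRecord(id="P", sequence=seq,
                               domain_spans=[("PF1", 1, 7)])
        cls = MotifClass("LIG_1", "LIG", "P.P", ("SH3",))
        hits = scan_motifs(inside, [cls])
        assert [(h.start, h.end) for h in hits] == [(11, 13)]


class TestMotifProbability:
    @pytest.mark.parametrize(
        "regex,expected",
        [
            ("...", 1.0),
            ("P.P", 0.0025),
            ("[ST]Q", 0.005),
            ("^P$", 0.05),
            ("A{3}", (1 / 20) ** 3),
            ("[^A]", 0.95),
        ],
    )
    def test_uniform_background_values(self, regex, expected):
        assert motif_probability(regex) == pytest.approx(expected)

    def test_unsupported_construct_named(self):
        with pytest.raises(ValueError, match=r"\("):
            motif_probability("(AB)+")

    @given(st.sets(st.sampled_from(AMINO_ACIDS), min_size=1, max_size=19),
           st.sampled_from(AMINO_ACIDS))
    @settings(max_examples=50, derandomize=True)
    def test_widening_a_character_class_never_decreases_probability(self, members, extra):
        base = f"[{''.join(sorted(members))}]Q"
        widened = f"[{''.join(sorted(members | {extra}))}]Q"
        assert motif_probability(widened) >= motif_probability(base)

    def test_probability_filter_is_monotone_in_cutoff(self):
        from modulin.classify import filter_classes_by_probability

        classes = [MotifClass(f"C{i}", "LIG", rx, ("D",))
                   for i, rx in enumerate(["P.P", "[ST]Q", "ACDEF", "A{4}.."])]
        cutoffs = [1e-7, 1e-5, 1e-3, 1.0]
        kept = [
            {c.class_id for c in filter_classes_by_probability(classes, cutoff=x)}
            for x in cutoffs
        ]
        for tighter, looser in zip(kept, kept[1:]):
            assert tighter <= looser


class TestClassifyEdges:
    def _setup(self):
        net = build_network([("P1", "P2"), ("P1", "P3"), ("P2", "P3")])
        inv = Inventories(
            domains={"P1": ["PF_A"], "P2": ["PF_B", "SH3"], "P3": []},
            motifs={"P1": ["LIG_1"], "P3": []},
        )
        classes = [MotifClass("LIG_1", "LIG", "P.P", ("SH3",))]
        catalog = {("PF_A", "PF_B")}
        return net, inv, classes, catalog

    def test_ddi_dli_and_unclassified(self):
        net, inv, classes, catalog = self._setup()
        # P1-P2 has both a catalog domain pair and motif->cognate evidence
        labelled = classify_edges(net, inv, catalog, classes)
        assert labelled.label_of("P1", "P2") == "unclassified"
        # featureless endpoints stay unclassified
        assert labelled.label_of("P2", "P3") == "unclassified"

    def test_pure_ddi_and_pure_dli(self):
        net = build_network([("P1", "P2"), ("P3", "P4")])
        inv = Inventories(
            domains={"P1": ["PF_A"], "P2": ["PF_B"], "P4": ["SH3"]},
            motifs={"P3": ["LIG_1"]},
        )
        classes = [MotifClass("LIG_1", "LIG", "P.P", ("SH3",))]
        labelled = classify_edges(net, inv, {("PF_A", "PF_B")}, classes)
        assert labelled.label_of("P1", "P2") == "DDI"
        assert labelled.label_of("P3", "P4") == "DLI"
        rec = next(r for r in labelled.edges() if r.key == ("P3", "P4"))
        assert rec.mediating_pairs == [("motif:LIG_1", "SH3")]

    def test_recovers_planted_labels_exactly(self, small_universe):
        u = small_universe
        labelled = classify_edges(u.network, u.inventories,
                                  u.catalogs.ddi_pairs, u.catalogs.motif_classes)
        mismatches = [r.key for r in labelled.edges()
                      if r.label != u.truth_labels[r.key]]
        assert mismatches == []


class TestHomoHetero:
    @pytest.mark.parametrize(
        "pairs,expected",
        [
            ([("PF1", "PF1")], "homo-DDI"),
            ([("PF1", "PF2")], "hetero-DDI"),
            ([("PF1", "PF2"), ("PF3", "PF3")], "homo-DDI"),
        ],
    )
    def test_split(self, pairs, expected):
        net = build_network([("P1", "P2", "DDI")])
        net.set_label("P1", "P2", "DDI", mediating_pairs=pairs)
        assert split_homo_hetero(net)[("P1", "P2")] == expected


class TestStageQuality:
    def test_fractions_and_baseline(self):
        universe = [f"m{i}" for i in range(100)]
        positives = set(universe[:20])
        stages = {
            "all": universe,
            "perfect": list(positives),
            "disjoint": universe[20:40],
        }
        result = stage_quality(stages, positives, universe, n_random=2000,
                               random_size=20, seed=3)
        assert result["perfect"].fraction == 1.0
        assert result["disjoint"].fraction == 0.0
        # hypergeometric: mean fraction = base rate, sd from draw variance
        base = 0.2
        sd = np.sqrt(base * 0.8 / 20 * (100 - 20) / 99)
        assert abs(result["all"].baseline_mean - base) < 3 * sd / np.sqrt(2000)
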