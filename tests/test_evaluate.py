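import math

import numpy as np
import pytest

from abrkit.evaluate import (EvaluationCounts, classify_ddg, compare_methods,
                             find_unique_binding_residues, macro_average,
                             per_region_stats, score_annotation)
from abrkit.regions import REGION_NAMES, REGION_ROLE, RegionAnnotation


def _ann(ab_id, scheme, spans):
    full = {r: None for r in REGION_NAMES}
    full.update(spans)
    return RegionAnnotation(ab_id, scheme, full)


def _random_ann(rng, ab_id, scheme):
    spans = {}
    for role, names in (("light", ("L1", "L2", "L3")),
                        ("heavy", ("H1", "H2", "H3"))):
        pos = 0
        for name in names:
            s = pos + int(rng.integers(1, 6))
            e = s + int(rng.integers(0, 8))
            spans[name] = (s, e)
            pos = e + 1
    return _ann(ab_id, scheme, spans)


def _random_gold(rng, n=20):
    return {(("heavy", "light")[int(rng.integers(2))], int(rng.integers(0, 60)))
            for _ in range(n)}


class TestScoring:
    def test_perfect_prediction(self):
        ann = _ann("a", "paratome", {"H1": (0, 4)})
        gold = {("heavy", i) for i in range(5)}
        counts, prec, rec = score_annotation(ann, gold)
        assert (prec, rec) == (1.0, 1.0)
        assert counts == EvaluationCounts(5, 0, 0)

    def test_half_right(self):
        # tp=2, fp=2, fn=2 -> precision 0.5, recall 0.5
        ann = _ann("a", "paratome", {"H1": (0, 3)})
        gold = {("heavy", 0), ("heavy", 1), ("heavy", 10), ("heavy", 11)}
        counts, prec, rec = score_annotation(ann, gold)
        assert counts == EvaluationCounts(2, 2, 2)
        assert prec == 0.5 and rec == 0.5

    @pytest.mark.parametrize("seed", range(10))
    def test_agrees_with_set_arithmetic(self, seed):
        rng = np.random.default_rng(seed)
        ann = _random_ann(rng, "a", "paratome")
        gold = _random_gold(rng)
        counts, prec, rec = score_annotation(ann, gold)
        p = ann.residues()
        assert counts.tp == len(p & gold)
        assert counts.fp == len(p - gold)
        assert counts.fn == len(gold - p)
        assert counts.tp + counts.fn == len(gold)
        assert counts.tp <= min(len(p), len(gold))
        if prec is not None:
            assert 0 <= prec <= 1
        assert 0 <= rec <= 1

    def test_empty_prediction(self):
        ann = _ann("a", "paratome", {})
        gold = {("heavy", 1)}
        _, prec, rec = score_annotation(ann, gold)
        assert prec is None and rec == 0.0

    def test_mismatched_antibody_ids_rejected(self):
        a = _ann("a", "paratome", {"H1": (0, 1)})
        b = _ann("b", "kabat", {"H1": (0, 1)})
        with pytest.raises(ValueError, match="different antibodies"):
            compare_methods(a, b, set())


class TestComparison:
    def test_identical_annotations(self):
        rng = np.random.default_rng(0)
        a = _random_ann(rng, "a", "paratome")
        b = _ann("a", "kabat", dict(a.spans))
        gold = _random_gold(rng)
        cmp = compare_methods(a, b, gold)
        assert cmp.delta_a == set() and cmp.delta_b == set()
        _, _, rec = score_annotation(a, gold)
        assert cmp.stats("consensus")["coverage"] == pytest.approx(rec)

    @pytest.mark.parametrize("seed", range(10))
    def test_set_algebra_identities(self, seed):
        rng = np.random.default_rng(100 + seed)
        a = _random_ann(rng, "a", "paratome")
        b = _random_ann(rng, "a", "kabat")
        gold = _random_gold(rng)
        cmp = compare_methods(a, b, gold)
        ra, rb = a.residues(), b.residues()
        assert cmp.consensus == ra & rb
        assert cmp.delta_a == ra - rb and cmp.delta_b == rb - ra
        # pairwise disjoint; unions rebuild the annotations
        assert not (cmp.consensus & cmp.delta_a)
        assert not (cmp.consensus & cmp.delta_b)
        assert not (cmp.delta_a & cmp.delta_b)
        assert cmp.consensus | cmp.delta_a == ra
        assert cmp.consensus | cmp.delta_b == rb

    @pytest.mark.parametrize("seed", range(5))
    def test_coverage_additivity(self, seed):
        # consensus + delta_a coverage = coverage of A's full annotation
        rng = np.random.default_rng(200 + seed)
        a = _random_ann(rng, "a", "paratome")
        b = _random_ann(rng, "a", "chothia")
        gold = _random_gold(rng)
        cmp = compare_methods(a, b, gold)
        cov_a = len(a.residues() & gold) / len(gold)
        total = (cmp.stats("consensus")["coverage"]
                 + cmp.stats("delta_a")["coverage"])
        assert total == pytest.approx(cov_a)

    def test_delta_semantics_on_nested_regions(self):
        # method B extends L1 three residues N-terminal of A, while A
        # extends L2 four residues C-terminal of B: each difference
        # appears in exactly one delta set
        a = _ann("ab", "paratome", {"L1": (3, 10), "L2": (20, 29)})
        b = _ann("ab", "kabat", {"L1": (0, 10), "L2": (20, 25)})
        cmp = compare_methods(a, b, set())
        assert cmp.delta_b == {("light", i) for i in (0, 1, 2)}
        assert cmp.delta_a == {("light", i) for i in (26, 27, 28, 29)}


class TestPerRegion:
    def test_single_region_holds_all_binding(self):
        ann = _ann("a", "paratome", {"H3": (10, 14)})
        gold = {("heavy", i) for i in range(10, 15)}
        df = per_region_stats(ann, gold)
        h3 = df[df.region == "H3"].iloc[0]
        assert h3.recall == 1.0 and h3.precision == 1.0

    @pytest.mark.parametrize("seed", range(5))
    def test_region_recalls_sum_to_total(self, seed):
        rng = np.random.default_rng(seed)
        ann = _random_ann(rng, "a", "paratome")
        gold = _random_gold(rng)
        df = per_region_stats(ann, gold)
        _, _, total = score_annotation(ann, gold)
        assert df.recall.sum() == pytest.approx(total)

    def test_hand_tallied_counts(self):
        ann = _ann("a", "kabat", {"L1": (0, 2), "H1": (5, 6)})
        gold = {("light", 0), ("light", 9), ("heavy", 5)}
        df = per_region_stats(ann, gold).set_index("region")
        assert df.loc["L1", "n_residues"] == 3
        assert df.loc["L1", "n_in_contact"] == 1
        assert df.loc["H1", "precision"] == pytest.approx(0.5)
        assert df.loc["H1", "recall"] == pytest.approx(1 / 3)


class TestUniqueResidues:
    def _cdrs(self, rng, spans=None):
        return [_ann("a", s, spans if spans is not None
                     else dict(_random_ann(rng, "a", s).spans))
                for s in ("kabat", "chothia", "imgt")]

    def test_identical_schemes_no_unique(self):
        rng = np.random.default_rng(0)
        par = _random_ann(rng, "a", "paratome")
        cdrs = self._cdrs(rng, dict(par.spans))
        pu, cu = find_unique_binding_residues(par, cdrs, _random_gold(rng))
        assert pu == set() and cu == set()

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_set_expression(self, seed):
        rng = np.random.default_rng(300 + seed)
        par = _random_ann(rng, "a", "paratome")
        cdrs = self._cdrs(rng)
        gold = _random_gold(rng)
        pu, cu = find_unique_binding_residues(par, cdrs, gold)
        union = set().union(*(c.residues() for c in cdrs))
        assert pu == (gold & par.residues()) - union
        assert cu == (gold & union) - par.residues()

    def test_missing_scheme_is_error(self):
        rng = np.random.default_rng(1)
        par = _random_ann(rng, "a", "paratome")
        cdrs = self._cdrs(rng)[:2]
        with pytest.raises(ValueError, match="missing CDR scheme: imgt"):
            find_unique_binding_residues(par, cdrs, set())


class TestDdg:
    @pytest.mark.parametrize("ddg,expected", [
        (0.30, "destabilizing"),
        (0.25, "neutral"),          # band is inclusive at the boundary
        (-0.25, "neutral"),
        (-0.30, "stabilizing"),
        (0.2500001, "destabilizing"),
        (0.0, "neutral"),
    ])
    def test_classification(self, ddg, expected):
        assert classify_ddg(ddg) == expected

    def test_every_finite_value_gets_exactly_one_class(self):
        for ddg in np.linspace(-2, 2, 401):
            assert classify_ddg(float(ddg)) in (
                "stabilizing", "neutral", "destabilizing")

    @pytest.mark.parametrize("bad", [math.nan, math.inf, -math.inf])
    def test_non_finite_rejected(self, bad):
        with pytest.raises(ValueError, match="finite"):
            classify_ddg(bad)


def test_macro_average_skips_undefined():
    assert macro_average([1.0, None, 0.0]) == 0.5
    assert macro_average([None]) is None
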