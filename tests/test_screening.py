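"""Unit tests for the ADME screen: similarity scores, criteria logic,
name normalization and the full screening assembly."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from herbnet.errors import (
    DimensionMismatchError,
    UndefinedSimilarityError,
    ValidationError,
)
from herbnet.screening import (
    CompoundRecord,
    ScreeningCriteria,
    drug_likeness,
    evaluate_criteria,
    normalize_name,
    screen_compounds,
    tanimoto,
)


def make_compound(cid="X1", name="test compound", herbs=("CG",), ob=50.0,
                  caco2=1.0, dl=0.5, **kw):
    return CompoundRecord(compound_id=cid, name=name, herbs=frozenset(herbs),
                          ob=ob, caco2=caco2, dl=dl, **kw)


class TestTanimoto:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            ((1, 2, 3), (1, 2, 3), 1.0),   # identical vectors
            ((1, 0), (0, 1), 0.0),          # orthogonal
            ((1, 1), (1, 0), 0.5),          # 1 / (2 + 1 - 1)
            ((2, 2), (1, 1), 2 / 3),        # 4 / (8 + 2 - 4)
        ],
    )
    def test_known_values(self, a, b, expected):
        assert tanimoto(a, b) == pytest.approx(expected, abs=1e-12)

    def test_dimension_mismatch(self):
        with pytest.raises(DimensionMismatchError):
            tanimoto((1, 2), (1, 2, 3))

    def test_both_zero_vectors(self):
        with pytest.raises(UndefinedSimilarityError):
            tanimoto((0, 0), (0, 0))

    def test_non_finite_rejected(self):
        with pytest.raises(ValidationError):
            tanimoto((1, float("nan")), (1, 1))

    # clamp tiny magnitudes: squaring subnormals underflows the denominator
    _coord = st.floats(0, 100, allow_nan=False).map(
        lambda x: 0.0 if x < 1e-6 else x
    )

    @settings(derandomize=True, max_examples=500, deadline=None)
    @given(st.lists(_coord, min_size=1, max_size=8), st.data())
    def test_symmetry_and_bounds(self, a, data):
        b = data.draw(
            st.lists(self._coord, min_size=len(a), max_size=len(a))
        )
        if not any(a) and not any(b):
            return
        f = tanimoto(a, b)
        assert f == tanimoto(b, a)  # exact symmetry
        assert 0.0 <= f <= 1.0

    @settings(derandomize=True, deadline=None)
    @given(st.lists(st.floats(0.1, 100), min_size=1, max_size=8))
    def test_self_similarity_is_one(self, a):
        assert tanimoto(a, a) == pytest.approx(1.0, abs=1e-12)

    def test_drug_likeness_delegates(self):
        ref = (1.0, 1.0)
        assert drug_likeness(ref, ref) == pytest.approx(1.0)
        assert drug_likeness((1, 0), (0, 1)) == 0.0
        assert drug_likeness((2, 2), (1, 1)) == pytest.approx(2 / 3)


class TestNormalizeName:
    @pytest.mark.parametrize(
        "raw, expected",
        [
            ("Senkyunolide-C", "senkyunolidec"),
            ("  Palmitic  acid ", "palmiticacid"),
            ("(Z)-Ligustilide", "zligustilide"),
        ],
    )
    def test_examples(self, raw, expected):
        assert normalize_name(raw) == expected

    def test_idempotent_on_random_strings(self):
        rng = np.random.default_rng(0)
        alphabet = list("abcXYZ 123-_,()[]*#/αβ")
        for _ in range(1000):
            s = "".join(rng.choice(alphabet, size=rng.integers(1, 30)))
            if not s.strip():
                continue
            once = normalize_name(s)
            if once:  # all-punctuation inputs normalize to ""
                assert normalize_name(once) == once

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            normalize_name("   ")


class TestEvaluateCriteria:
    def test_single_criterion_failure(self):
        # a high-OB, high-permeability compound failing only drug-likeness
        c = make_compound(ob=53.72, caco2=1.3, dl=0.07)
        ev = evaluate_criteria(c, ScreeningCriteria())
        assert not ev.overall
        assert set(ev.failing) == {"dl"}

    def test_two_criteria_failure(self):
        c = make_compound(ob=29.62, caco2=-0.44, dl=0.01)
        ev = evaluate_criteria(c, ScreeningCriteria())
        assert not ev.overall
        assert set(ev.failing) == {"caco2", "dl"}

    def test_inclusive_boundary_passes(self):
        c = make_compound(ob=15.0, caco2=-0.4, dl=0.08, mw=500.0,
                          hdon=5, hacc=10, alogp=5.0)
        ev = evaluate_criteria(c, ScreeningCriteria())
        assert ev.overall
        assert ev.failing == ()

    def test_missing_lipinski_fields_not_evaluated(self):
        ev = evaluate_criteria(make_compound(), ScreeningCriteria())
        assert ev.overall
        assert ev.flags["mw"] == "not_evaluated"
        assert ev.flags["hdon"] == "not_evaluated"

    def test_record_validation(self):
        with pytest.raises(ValidationError):
            make_compound(dl=1.5)
        with pytest.raises(ValidationError):
            make_compound(ob=-1.0)
        with pytest.raises(ValidationError):
            make_compound(hdon=-2)


class TestScreenCompounds:
    def test_fixture_yields_printed_active_count(
        self, per_herb_compounds, whitelist, target_index
    ):
        """Thresholds + whitelist rescue + duplicate merge + target filter
        reproduce the published 65-compound active set."""
        result = screen_compounds(per_herb_compounds, whitelist=whitelist,
                                  target_index=target_index)
        assert len(result) == 65
        provenance = [a.provenance for a in result.compounds]
        assert provenance.count("threshold_pass") == 46
        assert provenance.count("whitelist_rescued") == 19

    def test_cross_herb_duplicate_merged(self, per_herb_compounds, whitelist):
        result = screen_compounds(per_herb_compounds, whitelist=whitelist)
        by_name = {a.record.name: a.record for a in result.compounds}
        assert by_name["Adenine"].herbs == frozenset({"CG", "DG"})
        assert by_name["Palmitic acid"].herbs == frozenset({"CG", "DG"})
        merged = [e for e in result.exclusions
                  if e.reason.startswith("duplicate_merged_into:")]
        assert len(merged) == 8

    def test_all_below_threshold_all_excluded(self):
        db = [make_compound(cid=f"C{i}", name=f"cpd {i}", ob=5.0)
              for i in range(10)]
        result = screen_compounds(db, ScreeningCriteria(), whitelist=set())
        assert len(result) == 0
        assert all(e.reason == "threshold_fail" for e in result.exclusions)
        assert len(result.exclusions) == 10

    def test_no_target_exclusion(self):
        db = [make_compound(cid="A", name="alpha"),
              make_compound(cid="B", name="beta")]
        result = screen_compounds(db, target_index={"A": {"P1"}})
        assert result.active_ids == ["A"]
        assert result.exclusions == [type(result.exclusions[0])("B", "no_target")]

    def test_whitelist_rescues_subthreshold(self):
        db = [make_compound(cid="A", name="alpha", dl=0.01)]
        result = screen_compounds(db, whitelist={"Alpha"})
        assert len(result) == 1
        assert result.compounds[0].provenance == "whitelist_rescued"

    def test_conservation_of_records(self, per_herb_compounds, whitelist,
                                     target_index):
        result = screen_compounds(per_herb_compounds, whitelist=whitelist,
                                  target_index=target_index)
        accounted = {a.record.compound_id for a in result.compounds} | {
            e.compound_id for e in result.exclusions
        }
        assert len(accounted) == len(per_herb_compounds)
        # no compound on both sides
        assert not (
            {a.record.compound_id for a in result.compounds}
            & {e.compound_id for e in result.exclusions}
        )

    def test_empty_db_rejected(self):
        with pytest.raises(ValidationError):
            screen_compounds([])

    def test_deterministic(self, per_herb_compounds, whitelist, target_index):
        r1 = screen_compounds(per_herb_compounds, whitelist=whitelist,
                              target_index=target_index)
        r2 = screen_compounds(per_herb_compounds, whitelist=whitelist,
                              target_index=target_index)
        assert r1.active_ids == r2.active_ids
        assert r1.exclusions == r2.exclusions
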