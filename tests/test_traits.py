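"""Trait coding: composite colours, rarity filtering, matrix assembly."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from phylosyndrome import traits as tc
from phylosyndrome.traits import (
    EcologyRecord,
    ObserverScore,
    TraitMatrix,
    VocabularyError,
    build_trait_matrix,
    expand_composites,
    filter_rare_traits,
    read_ecology_csv,
    read_scores_csv,
    write_trait_matrix,
)

COLOURS = sorted(tc.COLOUR_VOCABULARY)


class TestExpandComposites:
    def test_three_colour_worked_example(self):
        # a yellow/black/white species carries six colour traits: the three
        # singles plus every two-colour combination
        out = expand_composites({"yellow", "black", "white"})
        assert out == {
            "yellow",
            "black",
            "white",
            "black/yellow",
            "black/white",
            "white/yellow",
        }
        assert len(out) == 6

    @pytest.mark.parametrize(
        "colours, expected",
        [
            ({"green"}, {"green"}),
            (set(), set()),
            ({"red", "black"}, {"red", "black", "black/red"}),
        ],
    )
    def test_small_sets(self, colours, expected):
        assert expand_composites(colours) == expected

    def test_unknown_colour_names_offender(self):
        with pytest.raises(VocabularyError, match="chartreuse"):
            expand_composites({"green", "chartreuse"})

    def test_more_than_three_colours_rejected(self):
        with pytest.raises(ValueError, match="at most 3"):
            expand_composites({"green", "red", "black", "white"})

    @given(st.sets(st.sampled_from(COLOURS), max_size=3))
    @settings(max_examples=100, deadline=None)
    def test_output_size_formula(self, colours):
        k = len(colours)
        assert len(expand_composites(colours)) == k + k * (k - 1) // 2

    @given(st.sets(st.sampled_from(COLOURS), min_size=2, max_size=3))
    @settings(max_examples=50, deadline=None)
    def test_pair_names_canonical(self, colours):
        for name in expand_composites(colours) - colours:
            a, _, b = name.partition("/")
            assert a < b  # lexicographic, never reversed
            assert {a, b} <= colours


def _matrix(values: dict[str, list[int]], classes: dict[str, str], species=None) -> TraitMatrix:
    n = len(next(iter(values.values())))
    idx = species or [f"s{i}" for i in range(n)]
    return TraitMatrix(
        data=pd.DataFrame(values, index=idx),
        trait_class=classes,
    )


class TestRarityFilter:
    def make(self, count_a: int, n: int = 10) -> TraitMatrix:
        a = [1] * count_a + [0] * (n - count_a)
        return _matrix(
            {"red": a, "stripe": [1] * n},
            {"red": tc.COLOUR_SINGLE, "stripe": tc.PATTERN},
        )

    def test_below_threshold_excluded(self):
        out, excl = filter_rare_traits(self.make(4), min_occurrences=5)
        assert excl == ["red"]
        assert "red" not in out.trait_names

    def test_at_threshold_retained(self):
        # "fewer than five" is strict: a column summing to exactly 5 stays
        out, excl = filter_rare_traits(self.make(5), min_occurrences=5)
        assert excl == []
        assert "red" in out.trait_names

    def test_identity_when_all_common(self):
        tm = self.make(8)
        out, excl = filter_rare_traits(tm, min_occurrences=5)
        assert excl == []
        assert out.data.equals(tm.data)

    def test_out_of_scope_columns_untouched(self):
        tm = _matrix(
            {"stripe": [1, 0, 0, 0, 0, 0]},
            {"stripe": tc.PATTERN},
        )
        out, excl = filter_rare_traits(tm, min_occurrences=5)
        assert "stripe" in out.trait_names and excl == []
        out, excl = filter_rare_traits(tm, min_occurrences=5, scope={tc.PATTERN})
        assert excl == ["stripe"]

    def test_idempotent(self):
        tm = self.make(3)
        once, _ = filter_rare_traits(tm, min_occurrences=5)
        twice, excl2 = filter_rare_traits(once, min_occurrences=5)
        assert twice.data.equals(once.data) and excl2 == []

    def test_min_occurrences_validated(self):
        with pytest.raises(ValueError):
            filter_rare_traits(self.make(4), min_occurrences=0)


def _score(sp, colours, patterns=frozenset(), obs="o1"):
    return ObserverScore(sp, obs, frozenset(colours), frozenset(patterns))


def _eco(sp, diet="oligophagous", tissue="leaves", forms=("forb",)):
    return EcologyRecord(sp, diet, tissue, frozenset(forms))


class TestBuildTraitMatrix:
    def test_direct_construction(self):
        scores = [_score(f"s{i}", {"green"}, {"stripe"}) for i in range(3)]
        eco = [_eco(f"s{i}") for i in range(3)]
        tm = build_trait_matrix(scores, eco, min_occurrences=1)
        assert tm.data["green"].sum() == 3
        assert tm.data["stripe"].sum() == 3
        assert tm.data["oligophagous"].sum() == 3
        assert tm.data["forb"].sum() == 3
        assert tm.data["woody"].sum() == 0
        # the green column disappears under the default rarity threshold
        tm5 = build_trait_matrix(scores, eco, min_occurrences=5)
        assert "green" not in tm5.trait_names
        assert "green" in tm5.excluded_traits

    def test_three_colour_species_fills_six_columns(self):
        scores = [_score(f"s{i}", {"yellow", "black", "white"}) for i in range(5)]
        tm = build_trait_matrix(scores, [], min_occurrences=5)
        for t in ("yellow", "black", "white", "black/yellow", "black/white", "white/yellow"):
            assert tm.data.loc["s0", t] == 1

    def test_pair_equals_and_of_components(self):
        rng = np.random.default_rng(42)
        scores = []
        for i in range(40):
            cols = set(rng.choice(COLOURS, size=rng.integers(0, 4), replace=False))
            scores.append(_score(f"s{i}", cols))
        tm = build_trait_matrix(scores, [], min_occurrences=1)
        for t in tm.columns_of_class(tc.COLOUR_PAIR):
            a, _, b = t.partition("/")
            expected = tm.data[a] & tm.data[b] if a in tm.data and b in tm.data else 0
            assert (tm.data[t] == expected).all()

    def test_duplicate_species_error(self):
        with pytest.raises(ValueError, match="duplicate species"):
            build_trait_matrix([_score("a", {"red"}), _score("a", {"red"})], [])

    def test_missing_ecology_recorded(self):
        tm = build_trait_matrix(
            [_score("a", {"red"}), _score("b", {"red"})],
            [_eco("a")],
            min_occurrences=1,
        )
        assert tm.missing_ecology == ["b"]

    def test_empty_input(self):
        tm = build_trait_matrix([], [], min_occurrences=1)
        assert tm.data.shape[0] == 0

    def test_multiple_growth_forms_one_hot(self):
        tm = build_trait_matrix(
            [_score("a", set())],
            [_eco("a", diet="polyphagous", forms=("forb", "woody"))],
            min_occurrences=1,
        )
        assert tm.data.loc["a", "forb"] == 1
        assert tm.data.loc["a", "woody"] == 1
        assert tm.data.loc["a", "graminoid"] == 0


class TestValidation:
    def test_observer_score_vocabulary(self):
        with pytest.raises(VocabularyError):
            ObserverScore("s", "o", frozenset({"mauve"}), frozenset())
        with pytest.raises(VocabularyError):
            ObserverScore("s", "o", frozenset(), frozenset({"zigzag"}))
        with pytest.raises(ValueError):
            ObserverScore("s", "o", frozenset({"red", "green", "blue", "pink"}), frozenset())

    def test_ecology_record_vocabulary(self):
        with pytest.raises(VocabularyError):
            EcologyRecord("s", "omnivorous", "leaves", frozenset({"forb"}))
        with pytest.raises(ValueError, match="non-empty"):
            EcologyRecord("s", "monophagous", "leaves", frozenset())

    def test_matrix_values_binary(self):
        with pytest.raises(ValueError, match="0/1"):
            _matrix({"red": [0, 2]}, {"red": tc.COLOUR_SINGLE})


class TestCsvRoundTrip:
    def test_scores_and_ecology(self, tmp_path):
        scores_csv = tmp_path / "scores.csv"
        scores_csv.write_text(
            "species,observer,colour1,colour2,colour3,band,blotch,spot,stipple,stripe\n"
            "s1,o1,green,yellow,,0,0,0,0,1\n"
            "s1,o2,green,,,0,0,0,0,1\n"
        )
        scores = read_scores_csv(scores_csv)
        assert len(scores) == 2
        assert scores[0].colours == {"green", "yellow"}
        assert scores[0].patterns == {"stripe"}

        eco_csv = tmp_path / "eco.csv"
        eco_csv.write_text(
            "species,diet_breadth,tissue,growth_forms\n"
            "s1,polyphagous,leaves,forb;woody\n"
        )
        eco = read_ecology_csv(eco_csv)
        assert eco[0].growth_forms == {"forb", "woody"}

    def test_duplicate_species_observer_rejected(self, tmp_path):
        f = tmp_path / "scores.csv"
        f.write_text(
            "species,observer,colour1,colour2,colour3,band,blotch,spot,stipple,stripe\n"
            "s1,o1,green,,,0,0,0,0,0\n"
            "s1,o1,red,,,0,0,0,0,0\n"
        )
        with pytest.raises(ValueError, match="duplicate"):
            read_scores_csv(f)

    def test_matrix_written_with_sidecar(self, tmp_path):
        tm = build_trait_matrix(
            [_score("a", {"red"}, {"band"})], [_eco("a")], min_occurrences=1
        )
        write_trait_matrix(tm, tmp_path / "m.csv", tmp_path / "m.json")
        back = pd.read_csv(tmp_path / "m.csv", index_col=0)
        assert back.loc["a", "red"] == 1
        import json

        meta = json.loads((tmp_path / "m.json").read_text())
        assert meta["trait_class"]["red"] == tc.COLOUR_SINGLE
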