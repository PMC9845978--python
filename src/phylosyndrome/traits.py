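"""Binary trait coding for larval colour, pattern and ecology data.

Raw data are per-species, per-observer scores: up to three salient body
colours from an 11-colour vocabulary, presence/absence of five pattern
elements, and host-use ecology (diet breadth, tissue consumed, host growth
form).  This module turns those scores into the species x trait 0/1 matrix
the comparative models consume:

* every scored single colour becomes a column;
* every unordered two-colour combination becomes a composite column
  (colour pairs can signal differently from their components — yellow with
  green is cryptic, yellow with black aposematic);
* three-colour combinations are never expanded;
* rare colour columns (fewer than ``min_occurrences`` species) are dropped;
* categorical ecology variables are one-hot expanded so every model is
  binary ~ binary.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

COLOUR_VOCABULARY = frozenset(
    {
        "brown",
        "green",
        "white",
        "red",
        "orange",
        "yellow",
        "black",
        "grey",
        "pink",
        "blue",
        "purple",
    }
)
PATTERN_VOCABULARY = frozenset({"stripe", "band", "spot", "stipple", "blotch"})
DIET_BREADTH_LEVELS = ("monophagous", "oligophagous", "polyphagous")
TISSUE_LEVELS = ("reproductive", "interior", "leaves", "other")
GROWTH_FORM_LEVELS = ("forb", "graminoid", "woody")

MAX_SALIENT_COLOURS = 3

#: trait-class labels used throughout the package
COLOUR_SINGLE = "colour_single"
COLOUR_PAIR = "colour_pair"
PATTERN = "pattern"
ECOLOGY = "ecology"

COLOUR_CLASSES = (COLOUR_SINGLE, COLOUR_PAIR)


class VocabularyError(ValueError):
    """A trait name falls outside the controlled vocabulary."""


@dataclass(frozen=True)
class ObserverScore:
    """One observer's colour/pattern scoring of one species."""

    species_id: str
    observer_id: str
    colours: frozenset[str]
    patterns: frozenset[str]

    def __post_init__(self) -> None:
        unknown = set(self.colours) - COLOUR_VOCABULARY
        if unknown:
            raise VocabularyError(
                f"unknown colour name(s) {sorted(unknown)} for species "
                f"{self.species_id!r}; allowed: {sorted(COLOUR_VOCABULARY)}"
            )
        if len(self.colours) > MAX_SALIENT_COLOURS:
            raise ValueError(
                f"species {self.species_id!r}: at most {MAX_SALIENT_COLOURS} "
                f"salient colours may be scored, got {len(self.colours)}"
            )
        unknown = set(self.patterns) - PATTERN_VOCABULARY
        if unknown:
            raise VocabularyError(
                f"unknown pattern name(s) {sorted(unknown)} for species "
                f"{self.species_id!r}; allowed: {sorted(PATTERN_VOCABULARY)}"
            )
        object.__setattr__(self, "colours", frozenset(self.colours))
        object.__setattr__(self, "patterns", frozenset(self.patterns))


@dataclass(frozen=True)
class EcologyRecord:
    """Host-use ecology of one species.

    ``growth_forms`` is a non-exclusive set: a polyphage feeding on both
    forbs and woody hosts carries a 1 in both one-hot columns.
    """

    species_id: str
    diet_breadth: str
    tissue: str
    growth_forms: frozenset[str]

    def __post_init__(self) -> None:
        if self.diet_breadth not in DIET_BREADTH_LEVELS:
            raise VocabularyError(
                f"unknown diet breadth {self.diet_breadth!r}; "
                f"allowed: {DIET_BREADTH_LEVELS}"
            )
        if self.tissue not in TISSUE_LEVELS:
            raise VocabularyError(
                f"unknown tissue type {self.tissue!r}; allowed: {TISSUE_LEVELS}"
            )
        forms = frozenset(self.growth_forms)
        if not forms:
            raise ValueError(
                f"species {self.species_id!r}: growth_forms must be non-empty"
            )
        unknown = forms - set(GROWTH_FORM_LEVELS)
        if unknown:
            raise VocabularyError(
                f"unknown growth form(s) {sorted(unknown)}; "
                f"allowed: {GROWTH_FORM_LEVELS}"
            )
        object.__setattr__(self, "growth_forms", forms)


def pair_name(a: str, b: str) -> str:
    """Canonical composite-colour name: lexicographic join with '/'."""
    if a == b:
        raise ValueError(f"a colour pair needs two distinct colours, got {a!r} twice")
    lo, hi = sorted((a, b))
    return f"{lo}/{hi}"


def expand_composites(colours: Iterable[str]) -> set[str]:
    """Expand a species' colour set into single + two-colour composite traits.

    A set of k colours (k <= 3) yields k single-colour traits plus
    k(k-1)/2 pair traits; three-colour combinations are never produced.
    Pair names are canonical (lexicographic, '/'-joined).
    """
    cols = set(colours)
    unknown = cols - COLOUR_VOCABULARY
    if unknown:
        raise VocabularyError(
            f"unknown colour name(s) {sorted(unknown)}; "
            f"allowed: {sorted(COLOUR_VOCABULARY)}"
        )
    if len(cols) > MAX_SALIENT_COLOURS:
        raise ValueError(
            f"at most {MAX_SALIENT_COLOURS} colours may be expanded, got {len(cols)}"
        )
    out = set(cols)
    for a, b in itertools.combinations(sorted(cols), 2):
        out.add(pair_name(a, b))
    return out


@dataclass
class TraitMatrix:
    """Species x binary-trait matrix plus per-trait class metadata.

    ``data`` is a 0/1 integer DataFrame indexed by species; ``trait_class``
    maps each column to one of colour_single / colour_pair / pattern /
    ecology.  ``missing_ecology`` lists species whose ecology was absent:
    they keep rows (colour/pattern columns valid) but are excluded from
    ecology-model fits by the pipeline.
    """

    data: pd.DataFrame
    trait_class: dict[str, str]
    missing_ecology: list[str] = field(default_factory=list)
    excluded_traits: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        vals = self.data.to_numpy()
        if vals.size and not np.isin(vals, (0, 1)).all():
            raise ValueError("trait matrix values must be 0/1")
        missing_meta = set(self.data.columns) - set(self.trait_class)
        if missing_meta:
            raise ValueError(f"traits without class metadata: {sorted(missing_meta)}")

    @property
    def species_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def trait_names(self) -> list[str]:
        return list(self.data.columns)

    def columns_of_class(self, *classes: str) -> list[str]:
        want = set(classes)
        return [c for c in self.data.columns if self.trait_class[c] in want]

    def values(self, trait: str) -> np.ndarray:
        return self.data[trait].to_numpy(dtype=float)

    def reordered(self, species_order: Sequence[str]) -> "TraitMatrix":
        return TraitMatrix(
            data=self.data.loc[list(species_order)],
            trait_class=dict(self.trait_class),
            missing_ecology=[s for s in self.missing_ecology if s in set(species_order)],
            excluded_traits=list(self.excluded_traits),
        )


def filter_rare_traits(
    matrix: TraitMatrix,
    min_occurrences: int = 5,
    scope: Iterable[str] = COLOUR_CLASSES,
) -> tuple[TraitMatrix, list[str]]:
    """Drop in-scope trait columns present in fewer than ``min_occurrences`` species.

    The threshold is strict ("fewer than"): a column whose sum equals
    ``min_occurrences`` survives.  By default only colour columns are in
    scope; pattern and ecology columns are never dropped unless the scope
    is widened.  Returns the filtered matrix and the excluded trait names.
    """
    if min_occurrences < 1:
        raise ValueError("min_occurrences must be >= 1")
    scope = set(scope)
    sums = matrix.data.sum(axis=0)
    excluded = [
        c
        for c in matrix.data.columns
        if matrix.trait_class[c] in scope and sums[c] < min_occurrences
    ]
    kept = [c for c in matrix.data.columns if c not in set(excluded)]
    out = TraitMatrix(
        data=matrix.data[kept],
        trait_class={c: matrix.trait_class[c] for c in kept},
        missing_ecology=list(matrix.missing_ecology),
        excluded_traits=list(matrix.excluded_traits) + excluded,
    )
    return out, excluded


def ecology_columns(record: EcologyRecord) -> dict[str, int]:
    """One-hot expansion of one species' ecology into binary columns."""
    cols: dict[str, int] = {}
    for level in DIET_BREADTH_LEVELS:
        cols[level] = int(record.diet_breadth == level)
    for level in TISSUE_LEVELS:
        cols[f"tissue_{level}"] = int(record.tissue == level)
    for level in GROWTH_FORM_LEVELS:
        cols[level] = int(level in record.growth_forms)
    return cols


def ecology_trait_names() -> list[str]:
    return (
        list(DIET_BREADTH_LEVELS)
        + [f"tissue_{t}" for t in TISSUE_LEVELS]
        + list(GROWTH_FORM_LEVELS)
    )


def build_trait_matrix(
    scores: Sequence[ObserverScore],
    ecology: Sequence[EcologyRecord] = (),
    min_occurrences: int = 5,
    rarity_scope: Iterable[str] = COLOUR_CLASSES,
    trait_universe: Sequence[str] | None = None,
    trait_class_universe: Mapping[str, str] | None = None,
) -> TraitMatrix:
    """Assemble the binary trait matrix from one score per species.

    Columns: observed single colours, observed (post-filter) colour pairs,
    the five pattern elements, and one-hot ecology levels.  When
    ``trait_universe`` is given the column set is frozen to it (no rarity
    filtering): this is how bootstrap replicates stay column-compatible.
    """
    seen: dict[str, ObserverScore] = {}
    for s in scores:
        if s.species_id in seen:
            raise ValueError(f"duplicate species in scores: {s.species_id!r}")
        seen[s.species_id] = s
    species = list(seen)

    eco_by_sp: dict[str, EcologyRecord] = {}
    for rec in ecology:
        if rec.species_id in eco_by_sp:
            raise ValueError(f"duplicate species in ecology: {rec.species_id!r}")
        eco_by_sp[rec.species_id] = rec

    rows: dict[str, dict[str, int]] = {}
    for sp in species:
        s = seen[sp]
        row: dict[str, int] = {}
        for trait in expand_composites(s.colours):
            row[trait] = 1
        for p in s.patterns:
            row[p] = 1
        if sp in eco_by_sp:
            row.update(ecology_columns(eco_by_sp[sp]))
        rows[sp] = row

    if trait_universe is not None:
        if trait_class_universe is None:
            raise ValueError("trait_universe requires trait_class_universe")
        columns = list(trait_universe)
        tclass = {c: trait_class_universe[c] for c in columns}
    else:
        colour_cols = sorted(
            {t for r in rows.values() for t in r if _colour_class(t) is not None}
        )
        pattern_cols = sorted(PATTERN_VOCABULARY)
        eco_cols = ecology_trait_names() if eco_by_sp else []
        columns = colour_cols + pattern_cols + eco_cols
        tclass = {}
        for c in colour_cols:
            tclass[c] = _colour_class(c)  # type: ignore[assignment]
        for c in pattern_cols:
            tclass[c] = PATTERN
        for c in eco_cols:
            tclass[c] = ECOLOGY

    data = pd.DataFrame(0, index=pd.Index(species, name="species"), columns=columns, dtype=int)
    for sp, row in rows.items():
        for trait, v in row.items():
            if trait in data.columns:
                data.loc[sp, trait] = v
    missing_eco = [sp for sp in species if sp not in eco_by_sp]

    tm = TraitMatrix(data=data, trait_class=tclass, missing_ecology=missing_eco)
    if trait_universe is None:
        tm, _ = filter_rare_traits(tm, min_occurrences=min_occurrences, scope=rarity_scope)
    return tm


def _colour_class(name: str) -> str | None:
    if name in COLOUR_VOCABULARY:
        return COLOUR_SINGLE
    if "/" in name:
        a, _, b = name.partition("/")
        if a in COLOUR_VOCABULARY and b in COLOUR_VOCABULARY and a < b:
            return COLOUR_PAIR
    return None


# ---------------------------------------------------------------------------
# CSV interfaces
# ---------------------------------------------------------------------------

SCORE_COLUMNS = (
    ["species", "observer", "colour1", "colour2", "colour3"]
    + sorted(PATTERN_VOCABULARY)
)


def read_scores_csv(path: str | Path) -> list[ObserverScore]:
    """Read per-(species, observer) colour/pattern scores.

    Expected columns: species, observer, colour1..colour3 (blank allowed),
    and one 0/1 column per pattern element.
    """
    df = pd.read_csv(path, dtype={"species": str, "observer": str})
    required = {"species", "observer"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"scores file missing columns: {sorted(missing)}")
    out = []
    seen: set[tuple[str, str]] = set()
    for _, row in df.iterrows():
        key = (row["species"], row["observer"])
        if key in seen:
            raise ValueError(f"duplicate (species, observer) row: {key}")
        seen.add(key)
        colours = frozenset(
            str(row[c]).strip()
            for c in ("colour1", "colour2", "colour3")
            if c in df.columns and pd.notna(row[c]) and str(row[c]).strip()
        )
        patterns = frozenset(
            p for p in PATTERN_VOCABULARY if p in df.columns and int(row[p]) == 1
        )
        out.append(
            ObserverScore(
                species_id=row["species"],
                observer_id=row["observer"],
                colours=colours,
                patterns=patterns,
            )
        )
    return out


def read_ecology_csv(path: str | Path) -> list[EcologyRecord]:
    """Read per-species ecology: diet_breadth, tissue, growth_forms (';'-joined)."""
    df = pd.read_csv(path, dtype=str)
    missing = {"species", "diet_breadth", "tissue", "growth_forms"} - set(df.columns)
    if missing:
        raise ValueError(f"ecology file missing columns: {sorted(missing)}")
    out = []
    for _, row in df.iterrows():
        forms = frozenset(
            f.strip() for f in str(row["growth_forms"]).split(";") if f.strip()
        )
        out.append(
            EcologyRecord(
                species_id=row["species"],
                diet_breadth=row["diet_breadth"],
                tissue=row["tissue"],
                growth_forms=forms,
            )
        )
    return out


def write_trait_matrix(matrix: TraitMatrix, csv_path: str | Path, sidecar_path: str | Path | None = None) -> None:
    """Write the 0/1 matrix as CSV plus a JSON sidecar of metadata."""
    matrix.data.to_csv(csv_path)
    if sidecar_path is not None:
        meta = {
            "trait_class": matrix.trait_class,
            "excluded_traits": matrix.excluded_traits,
            "missing_ecology": matrix.missing_ecology,
        }
        Path(sidecar_path).write_text(json.dumps(meta, indent=2, sort_keys=True))
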