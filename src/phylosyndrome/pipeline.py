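"""Trait-pair model enumeration, FDR, observer bootstrap, consensus edges.

The analysis asks, for every (coloration, pattern/ecology) trait pair,
whether the pair co-evolves: each pair is a bivariate phylogenetic
logistic regression, p-values are Benjamini-Hochberg adjusted within the
*a priori* and exploratory hypothesis families separately, and the whole
analysis is repeated over B bootstrap datasets in which one observer's
colour/pattern scores are drawn per species.  An association is reported
("supported") only when it is FDR-significant — with the same coefficient
sign as the full-data fit — in at least a consensus fraction (default
90%) of converged bootstrap replicates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import dendropy
import networkx as nx
import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from . import traits as tc
from .phylo import match_tips, patristic_matrix
from .phyloglm import (
    PhyloGLMFit,
    alpha_grid,
    batch_fit_bivariate,
    fit_phyloglm,
    grid_cholesky,
)

A_PRIORI = "a_priori"
EXPLORATORY = "exploratory"


@dataclass(frozen=True)
class ModelSpec:
    """One bivariate model: binary response ~ intercept + binary predictor."""

    response: str
    predictor: str
    subset: str = EXPLORATORY
    hypothesis_tag: str = ""

    def __post_init__(self) -> None:
        if self.response == self.predictor:
            raise ValueError(f"response equals predictor: {self.response!r}")
        if self.subset not in (A_PRIORI, EXPLORATORY):
            raise ValueError(f"subset must be a_priori or exploratory, got {self.subset!r}")


@dataclass
class PipelineConfig:
    """Analysis settings; defaults mirror the study design.

    ``a_priori_pairs`` lists literature-predicted trait pairs (unordered);
    any enumerated model whose {response, predictor} matches one is tagged
    a_priori, everything else exploratory.  ``direction`` controls which
    side of a cross-class pair is the response: by default coloration
    responds to pattern/ecology ("colour_response"); "reversed" swaps it
    for sensitivity checks.
    """

    n_bootstrap: int = 1000
    consensus_threshold: float = 0.90
    alpha_level: float = 0.05
    seed: int = 0
    a_priori_pairs: list[tuple[str, str]] = field(default_factory=list)
    direction: str = "colour_response"
    fdr_scope: str = "subset"  # or "global"
    sign_consistency: bool = True
    min_occurrences: int = 5
    refilter_per_replicate: bool = False
    alpha_bounds: tuple[float, float] = (1e-3, 1e3)
    alpha_grid_size: int = 13
    include_colour_pattern: bool = True
    include_colour_ecology: bool = True
    include_pattern_ecology: bool = True
    explicit_pairs: list[tuple[str, str]] | None = None  # (response, predictor)

    def __post_init__(self) -> None:
        if self.n_bootstrap < 1:
            raise ValueError("n_bootstrap must be >= 1")
        if not 0 < self.consensus_threshold <= 1:
            raise ValueError("consensus_threshold must lie in (0, 1]")
        if not 0 < self.alpha_level < 1:
            raise ValueError("alpha_level must lie in (0, 1)")
        if self.fdr_scope not in ("subset", "global"):
            raise ValueError("fdr_scope must be 'subset' or 'global'")
        if self.direction not in ("colour_response", "reversed"):
            raise ValueError("direction must be 'colour_response' or 'reversed'")


@dataclass
class AssociationResult:
    """Consensus outcome for one trait pair."""

    spec: ModelSpec
    full_data_fit: PhyloGLMFit
    sign: int
    support: float
    supported: bool
    replicates_used: int
    reliable: bool
    replicate_adjusted_p: np.ndarray = field(default_factory=lambda: np.array([]))

    def to_dict(self) -> dict:
        return {
            "response": self.spec.response,
            "predictor": self.spec.predictor,
            "subset": self.spec.subset,
            "hypothesis_tag": self.spec.hypothesis_tag,
            "sign": int(self.sign),
            "support": float(self.support),
            "supported": bool(self.supported),
            "replicates_used": int(self.replicates_used),
            "reliable": bool(self.reliable),
            "full_data_fit": self.full_data_fit.to_dict(),
        }


# ---------------------------------------------------------------------------
# model enumeration and FDR
# ---------------------------------------------------------------------------


def enumerate_models(matrix: tc.TraitMatrix, config: PipelineConfig) -> list[ModelSpec]:
    """All bivariate trait-pair models, tagged a_priori vs exploratory.

    Colour ~ pattern pairs test colour/pattern syndromes; colour ~ ecology
    and pattern ~ ecology pairs test the host-plant hypotheses.  The
    a-priori list is config data (unordered pairs).  When
    ``config.explicit_pairs`` is set, exactly those (response, predictor)
    models are built instead of the full cross-class enumeration.
    """
    colour = matrix.columns_of_class(tc.COLOUR_SINGLE, tc.COLOUR_PAIR)
    pattern = matrix.columns_of_class(tc.PATTERN)
    ecology = matrix.columns_of_class(tc.ECOLOGY)

    known = set(matrix.trait_names)
    bad = sorted(
        {t for pair in config.a_priori_pairs for t in pair if t not in known}
    )
    if bad:
        raise ValueError(f"a-priori config references unknown traits: {bad}")
    apriori = {frozenset(p) for p in config.a_priori_pairs}

    if config.explicit_pairs is not None:
        bad = sorted(
            {t for pair in config.explicit_pairs for t in pair if t not in known}
        )
        if bad:
            raise ValueError(f"explicit model list references unknown traits: {bad}")
        return [
            ModelSpec(
                response=r,
                predictor=p,
                subset=A_PRIORI if frozenset({r, p}) in apriori else EXPLORATORY,
            )
            for r, p in config.explicit_pairs
        ]

    def make(resp: str, pred: str) -> ModelSpec:
        if config.direction == "reversed":
            resp, pred = pred, resp
        subset = A_PRIORI if frozenset({resp, pred}) in apriori else EXPLORATORY
        return ModelSpec(response=resp, predictor=pred, subset=subset)

    specs: list[ModelSpec] = []
    if config.include_colour_pattern:
        specs += [make(c, p) for c in colour for p in pattern]
    if config.include_colour_ecology:
        specs += [make(c, e) for c in colour for e in ecology]
    if config.include_pattern_ecology:
        specs += [make(p, e) for p in pattern for e in ecology]
    return specs


def is_supported(support: float, threshold: float) -> bool:
    """Consensus rule: supported iff support >= threshold (inclusive)."""
    return support >= threshold


def fdr_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# observer bootstrap
# ---------------------------------------------------------------------------


def _pooled_union_matrix(
    scores: Sequence[tc.ObserverScore],
    ecology: Sequence[tc.EcologyRecord],
    min_occurrences: int,
) -> tuple[tc.TraitMatrix, dict[str, list[tc.ObserverScore]]]:
    """Pooled (OR-over-observers) matrix; fixes the trait universe."""
    by_species: dict[str, list[tc.ObserverScore]] = {}
    for s in scores:
        by_species.setdefault(s.species_id, []).append(s)
    species = list(by_species)

    eco_by_sp = {r.species_id: r for r in ecology}
    rows: dict[str, dict[str, int]] = {}
    for sp, recs in by_species.items():
        row: dict[str, int] = {}
        for rec in recs:
            for t in tc.expand_composites(rec.colours):
                row[t] = 1
            for pat in rec.patterns:
                row[pat] = 1
        if sp in eco_by_sp:
            row.update(tc.ecology_columns(eco_by_sp[sp]))
        rows[sp] = row

    colour_cols = sorted(
        {t for r in rows.values() for t in r if tc._colour_class(t) is not None}
    )
    pattern_cols = sorted(tc.PATTERN_VOCABULARY)
    eco_cols = tc.ecology_trait_names() if eco_by_sp else []
    columns = colour_cols + pattern_cols + eco_cols
    tclass: dict[str, str] = {}
    for c in colour_cols:
        tclass[c] = tc._colour_class(c)  # type: ignore[assignment]
    for c in pattern_cols:
        tclass[c] = tc.PATTERN
    for c in eco_cols:
        tclass[c] = tc.ECOLOGY

    data = pd.DataFrame(0, index=pd.Index(species, name="species"), columns=columns, dtype=int)
    for sp, row in rows.items():
        for t, v in row.items():
            data.loc[sp, t] = v
    missing_eco = [sp for sp in species if sp not in eco_by_sp]
    tm = tc.TraitMatrix(data=data, trait_class=tclass, missing_ecology=missing_eco)
    tm, _ = tc.filter_rare_traits(tm, min_occurrences=min_occurrences)
    return tm, by_species


def _observer_trait_stack(
    by_species: dict[str, list[tc.ObserverScore]],
    species_order: Sequence[str],
    columns: Sequence[str],
) -> tuple[np.ndarray, np.ndarray]:
    """(n_species, n_traits, max_obs) per-observer colour/pattern values.

    Ecology columns are zero here; the caller overlays them (they do not
    vary by observer).  Also returns the per-species observer count.
    """
    n = len(species_order)
    T = len(columns)
    col_index = {c: j for j, c in enumerate(columns)}
    counts = np.array([len(by_species[sp]) for sp in species_order], dtype=int)
    K = int(counts.max())
    stack = np.zeros((n, T, K), dtype=np.int8)
    for i, sp in enumerate(species_order):
        recs = by_species[sp]
        for k in range(K):
            rec = recs[k % len(recs)]  # repeat if a species has fewer observers
            for t in tc.expand_composites(rec.colours):
                j = col_index.get(t)
                if j is not None:
                    stack[i, j, k] = 1
            for pat in rec.patterns:
                j = col_index.get(pat)
                if j is not None:
                    stack[i, j, k] = 1
    return stack, counts


def run_full_analysis(
    scores: Sequence[tc.ObserverScore],
    ecology: Sequence[tc.EcologyRecord],
    tree: dendropy.Tree,
    config: PipelineConfig,
) -> list[AssociationResult]:
    """The whole study pipeline: coding, fits, FDR, bootstrap, consensus.

    Per replicate b: draw one observer per species (seeded substreams),
    rebuild the 0/1 matrix on the trait universe frozen from the pooled
    data, fit every model, BH-adjust within each hypothesis family, and
    record whether each pair is significant with the full-data sign.
    """
    if not scores:
        raise ValueError("no observer scores provided")
    pooled, by_species = _pooled_union_matrix(scores, ecology, config.min_occurrences)
    tree, pooled, report = match_tips(tree, pooled)
    dist = patristic_matrix(tree, normalize=True)
    species_order = pooled.species_ids

    specs = enumerate_models(pooled, config)
    if not specs:
        return []

    eco_ok = np.array(
        [sp not in set(pooled.missing_ecology) for sp in species_order], dtype=bool
    )
    is_eco_spec = np.array(
        [
            pooled.trait_class[s.response] == tc.ECOLOGY
            or pooled.trait_class[s.predictor] == tc.ECOLOGY
            for s in specs
        ],
        dtype=bool,
    )

    # --- full-data fits (precise, per spec) ---
    full_fits: list[PhyloGLMFit | None] = []
    full_sign = np.zeros(len(specs), dtype=int)
    for j, s in enumerate(specs):
        mask = eco_ok if is_eco_spec[j] else np.ones(len(species_order), dtype=bool)
        y = pooled.values(s.response)[mask]
        x = pooled.values(s.predictor)[mask]
        sub = dist.matrix[np.ix_(mask.nonzero()[0], mask.nonzero()[0])]
        try:
            fit = fit_phyloglm(
                y,
                x,
                sub,
                coef_names=["intercept", s.predictor],
                alpha_bounds=config.alpha_bounds,
            )
        except (ValueError, np.linalg.LinAlgError):
            fit = None
        full_fits.append(fit)
        full_sign[j] = 0 if fit is None else int(np.sign(fit.beta[1]))

    # --- bootstrap ---
    B = config.n_bootstrap
    grid = alpha_grid(config.alpha_bounds, config.alpha_grid_size)
    masks: dict[bool, np.ndarray] = {False: np.ones(len(species_order), dtype=bool)}
    if is_eco_spec.any():
        masks[True] = eco_ok
    chols = {
        key: grid_cholesky(dist.matrix[np.ix_(m.nonzero()[0], m.nonzero()[0])], grid)
        for key, m in masks.items()
        if m.any()
    }

    cp_cols = pooled.columns_of_class(tc.COLOUR_SINGLE, tc.COLOUR_PAIR, tc.PATTERN)
    stack, counts = _observer_trait_stack(by_species, species_order, cp_cols)
    col_of = {c: j for j, c in enumerate(cp_cols)}
    pooled_vals = {c: pooled.values(c) for c in pooled.trait_names}

    ss = np.random.SeedSequence(config.seed)
    child_seeds = ss.spawn(B)

    n_spec = len(specs)
    sig_counts = np.zeros(n_spec, dtype=int)
    used_counts = np.zeros(n_spec, dtype=int)
    rep_adj_p = np.full((B, n_spec), np.nan)

    fam_idx: dict[str, np.ndarray] = {}
    if config.fdr_scope == "subset":
        for fam in (A_PRIORI, EXPLORATORY):
            fam_idx[fam] = np.array([j for j, s in enumerate(specs) if s.subset == fam], dtype=int)
    else:
        fam_idx["all"] = np.arange(n_spec)

    n_sp = len(species_order)
    for b in range(B):
        rng = np.random.default_rng(child_seeds[b])
        choice = (rng.uniform(size=n_sp) * counts).astype(int)
        rep_cp = stack[
            np.arange(n_sp)[:, None], np.arange(len(cp_cols))[None, :], choice[:, None]
        ]

        def col(name: str) -> np.ndarray:
            j = col_of.get(name)
            if j is not None:
                return rep_cp[:, j].astype(float)
            return pooled_vals[name]  # ecology columns don't vary by observer

        dropped: set[str] = set()
        if config.refilter_per_replicate:
            for c in cp_cols:
                if pooled.trait_class[c] in tc.COLOUR_CLASSES and col(c).sum() < config.min_occurrences:
                    dropped.add(c)

        raw_p = np.full(n_spec, np.nan)
        sign = np.zeros(n_spec, dtype=int)
        conv = np.zeros(n_spec, dtype=bool)
        for key, m in masks.items():
            idx = [j for j in range(n_spec) if is_eco_spec[j] == key]
            if not idx:
                continue
            live = [
                j
                for j in idx
                if specs[j].response not in dropped and specs[j].predictor not in dropped
            ]
            if not live:
                continue
            Y = np.column_stack([col(specs[j].response)[m] for j in live])
            X = np.column_stack([col(specs[j].predictor)[m] for j in live])
            res = batch_fit_bivariate(Y, X, chols[key])
            for t, j in enumerate(live):
                raw_p[j] = res.p1[t]
                sign[j] = int(np.sign(res.beta1[t])) if res.valid[t] else 0
                conv[j] = bool(res.converged[t])

        for fam, idx in fam_idx.items():
            live = idx[conv[idx] & np.isfinite(raw_p[idx])]
            if live.size == 0:
                continue
            adj = fdr_adjust(raw_p[live])
            rep_adj_p[b, live] = adj
            for t, j in enumerate(live):
                used_counts[j] += 1
                ok_sign = (not config.sign_consistency) or (sign[j] == full_sign[j] != 0)
                if adj[t] < config.alpha_level and ok_sign:
                    sig_counts[j] += 1

    results: list[AssociationResult] = []
    for j, s in enumerate(specs):
        fit = full_fits[j]
        if fit is None:
            fit = PhyloGLMFit(
                beta=np.full(2, np.nan),
                se=np.full(2, np.nan),
                alpha=float("nan"),
                p_values=np.full(2, np.nan),
                converged=False,
                alpha_at_bound=False,
                n_tips=0,
                coef_names=["intercept", s.predictor],
            )
        used = int(used_counts[j])
        support = float(sig_counts[j] / used) if used else 0.0
        results.append(
            AssociationResult(
                spec=s,
                full_data_fit=fit,
                sign=int(full_sign[j]),
                support=support,
                supported=bool(used and is_supported(support, config.consensus_threshold)),
                replicates_used=used,
                reliable=used >= B / 2,
                replicate_adjusted_p=rep_adj_p[:, j],
            )
        )
    return results


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------


def export_association_network(
    results: Sequence[AssociationResult],
    out_dir: str | Path,
    trait_class: dict[str, str] | None = None,
) -> tuple[Path, Path]:
    """Write edges.csv (supported associations) and a node-link graph JSON.

    Node classes mirror the figure convention: colours are circles,
    patterns squares, ecology diamonds.  Unsupported pairs still appear in
    the accompanying results (support is always reported) but contribute
    no edge.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = [
        {
            "response": r.spec.response,
            "predictor": r.spec.predictor,
            "sign": "+" if r.sign > 0 else ("-" if r.sign < 0 else "0"),
            "support": f"{r.support:.4f}",
            "subset": r.spec.subset,
            "supported": int(r.supported),
        }
        for r in results
        if r.supported
    ]
    edges_path = out_dir / "edges.csv"
    pd.DataFrame(
        rows, columns=["response", "predictor", "sign", "support", "subset", "supported"]
    ).to_csv(edges_path, index=False)

    shapes = {
        tc.COLOUR_SINGLE: "circle",
        tc.COLOUR_PAIR: "circle",
        tc.PATTERN: "square",
        tc.ECOLOGY: "diamond",
    }
    G = nx.Graph()
    for r in results:
        if not r.supported:
            continue
        for t in (r.spec.response, r.spec.predictor):
            cls = (trait_class or {}).get(t, "")
            G.add_node(t, trait_class=cls, shape=shapes.get(cls, "circle"))
        G.add_edge(
            r.spec.response,
            r.spec.predictor,
            sign="+" if r.sign > 0 else "-",
            support=round(r.support, 4),
            subset=r.spec.subset,
        )
    graph_path = out_dir / "network.json"
    graph_path.write_text(json.dumps(nx.node_link_data(G, edges="edges"), indent=2, sort_keys=True))
    return edges_path, graph_path


def results_to_json(results: Sequence[AssociationResult], path: str | Path) -> None:
    Path(path).write_text(
        json.dumps([r.to_dict() for r in results], indent=2, sort_keys=True)
    )
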