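"""Synthetic phylogenies, traits and observer noise.

Everything the analysis pipeline consumes can be generated here with
known ground truth: ultrametric trees (Yule or birth-death), binary
predictor traits with phylogenetic structure (clade blocks or a two-state
Markov switch), binary responses with a planted log-odds effect, and two
observers whose colour/pattern scores disagree at a controlled rate.

The response generator is a latent-Gaussian threshold scheme: draw
z ~ MVN(0, R(alpha_true)) on the tree's patristic distances, then set
y_i = 1 iff Phi(z_i) < logistic(beta0 + beta1 x_i).  Because Phi(z_i) is
marginally Uniform(0,1), the marginal success probability is exactly
logistic(beta0 + beta1 x_i) under any covariate, while between-tip
correlation decays with distance.  The correlation SHAPE differs from the
two-state switching process the regression assumes — that mismatch is
deliberate realism.  An exact switching-process generator (constant mean,
no covariates) is provided for pure signal-recovery checks.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field, asdict

import dendropy
import numpy as np
from dendropy.simulate import treesim
from scipy.special import expit, ndtr
from scipy import linalg

from .phylo import PatristicDistances, patristic_matrix, validate_tree
from .traits import (
    COLOUR_VOCABULARY,
    MAX_SALIENT_COLOURS,
    PATTERN_VOCABULARY,
    EcologyRecord,
    ObserverScore,
)


@dataclass
class SimConfig:
    """Full parameterization of one synthetic dataset.

    beta_true is (intercept, effect) in log-odds units; alpha_true is the
    signal parameter on the height-1 tree (large = independent tips);
    disagreement_rate is the per-trait probability that an observer's
    score toggles relative to the truth.
    """

    n_tips: int = 300
    tree_model: str = "yule"  # or "birth_death"
    birth_rate: float = 1.0
    death_rate: float = 0.0
    alpha_true: float = 4.0
    beta_true: tuple[float, float] = (-1.0, 1.5)
    predictor_model: str = "mk_switch"  # or "clade_block"
    mk_rate: float = 2.0
    disagreement_rate: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tips < 4:
            raise ValueError("n_tips must be >= 4")
        if not 0.0 <= self.disagreement_rate <= 1.0:
            raise ValueError("disagreement_rate must lie in [0, 1]")
        if self.birth_rate <= 0:
            raise ValueError("birth_rate must be > 0")
        if self.tree_model not in ("yule", "birth_death"):
            raise ValueError(f"unknown tree model {self.tree_model!r}")
        if self.predictor_model not in ("mk_switch", "clade_block"):
            raise ValueError(f"unknown predictor model {self.predictor_model!r}")
        if self.alpha_true < 0:
            raise ValueError("alpha_true must be >= 0")

    def to_dict(self) -> dict:
        return asdict(self)


def simulate_tree(config: SimConfig) -> dendropy.Tree:
    """Ultrametric tree under Yule / birth-death, height normalized to 1."""
    if config.tree_model == "birth_death" and config.birth_rate <= config.death_rate:
        raise ValueError(
            "birth_death requires birth_rate > death_rate (unconditioned "
            "simulation would not reach the target tip count)"
        )
    death = 0.0 if config.tree_model == "yule" else config.death_rate
    rng = random.Random(config.seed)
    tree = treesim.birth_death_tree(
        birth_rate=config.birth_rate,
        death_rate=death,
        num_extant_tips=config.n_tips,
        rng=rng,
    )
    # the process stops at the instant of the n-th split, leaving a
    # zero-length cherry; run the clock to the next (uncounted) event so
    # every terminal branch is positive and no two tips coincide
    extra = rng.expovariate(config.n_tips * config.birth_rate)
    for leaf in tree.leaf_node_iter():
        leaf.edge.length = (leaf.edge.length or 0.0) + extra
    for i, leaf in enumerate(tree.leaf_node_iter()):
        leaf.taxon.label = f"t{i}"
    _normalize_height(tree)
    return validate_tree(tree)


def _normalize_height(tree: dendropy.Tree) -> None:
    depths = tree.calc_node_root_distances(return_leaf_distances_only=True)
    h = max(depths)
    if h <= 0:
        raise ValueError("degenerate tree of zero height")
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length = edge.length / h


def simulate_predictor(
    tree: dendropy.Tree, config: SimConfig, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Binary predictor per tip (tip order = tree leaf order).

    ``clade_block`` marks one clade spanning 30-70% of tips; if no internal
    node falls in that window it falls back to the Markov switch with a
    warning.  ``mk_switch`` runs a symmetric two-state process at
    ``mk_rate`` per unit branch length from a uniform root state.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    leaves = tree.leaf_nodes()
    n = len(leaves)
    if config.predictor_model == "clade_block":
        lo, hi = 0.3 * n, 0.7 * n
        candidates = [
            nd
            for nd in tree.preorder_internal_node_iter()
            if nd is not tree.seed_node and lo <= len(nd.leaf_nodes()) <= hi
        ]
        if not candidates:
            import warnings

            warnings.warn(
                "no internal clade spans 30-70% of tips; falling back to mk_switch",
                stacklevel=2,
            )
        else:
            block = candidates[rng.integers(len(candidates))]
            inside = {id(lf) for lf in block.leaf_nodes()}
            return np.array([1 if id(lf) in inside else 0 for lf in leaves], dtype=int)
    return simulate_switching_trait(
        tree, rate=config.mk_rate, stationary_p=0.5, rng=rng, root_state=None
    )


def simulate_switching_trait(
    tree: dendropy.Tree,
    rate: float,
    stationary_p: float = 0.5,
    rng: np.random.Generator | None = None,
    root_state: int | None = None,
) -> np.ndarray:
    """Exact two-state switching process along branches.

    Transition rates q01 = rate * p, q10 = rate * (1 - p) give stationary
    frequency ``stationary_p`` of state 1 and between-tip correlation
    exp(-rate * d) — the same form the regression's working correlation
    assumes, which makes this the generator of choice for pure
    signal-parameter recovery checks.
    """
    if rate < 0:
        raise ValueError("rate must be >= 0")
    if rng is None:
        rng = np.random.default_rng(0)
    p = stationary_p
    states: dict = {}
    root = tree.seed_node
    if root_state is None:
        states[root] = int(rng.uniform() < p)
    else:
        states[root] = int(root_state)

    def transition(state: int, t: float) -> int:
        if rate == 0 or t <= 0:
            return state
        decay = math.exp(-rate * t)
        p1 = p + (state - p) * decay  # P(state 1 at end | start)
        return int(rng.uniform() < p1)

    out = np.empty(len(tree.leaf_nodes()), dtype=int)
    i = 0
    for node in tree.preorder_node_iter():
        if node is root:
            continue
        states[node] = transition(states[node.parent_node], node.edge.length or 0.0)
        if node.is_leaf():
            out[i] = states[node]
            i += 1
    return out


def simulate_response(
    dist: PatristicDistances,
    predictor: np.ndarray,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Binary response with exact logistic margins and decaying correlation.

    y_i = 1 iff Phi(z_i) < logistic(beta0 + beta1 x_i), z ~ MVN(0, R(alpha_true)).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)
    x = np.asarray(predictor, dtype=float)
    if x.shape[0] != dist.n_tips:
        raise ValueError("predictor not aligned with distance matrix")
    b0, b1 = config.beta_true
    R = np.exp(-config.alpha_true * dist.matrix)
    try:
        L = linalg.cholesky(R + 1e-10 * np.eye(dist.n_tips), lower=True)
    except linalg.LinAlgError as exc:
        raise ValueError(f"latent correlation matrix not PSD: {exc}") from exc
    z = L @ rng.standard_normal(dist.n_tips)
    u = ndtr(z)  # marginally Uniform(0, 1)
    return (u < expit(b0 + b1 * x)).astype(int)


# ---------------------------------------------------------------------------
# Observer scoring noise
# ---------------------------------------------------------------------------


@dataclass
class TrueScores:
    """Ground-truth colour/pattern sets per species (pre observer noise)."""

    species_ids: list[str]
    colours: dict[str, frozenset]
    patterns: dict[str, frozenset]


def simulate_observers(
    truth: TrueScores,
    config: SimConfig,
    observer_ids: tuple[str, str] = ("obs1", "obs2"),
    rng: np.random.Generator | None = None,
) -> list[ObserverScore]:
    """Two observers, each the truth with per-trait independent toggles.

    A toggle adds or removes the trait with probability
    ``disagreement_rate``.  If toggling pushes a species over the
    three-colour cap, one colour is evicted at random.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 3)
    rate = config.disagreement_rate
    out: list[ObserverScore] = []
    colour_names = sorted(COLOUR_VOCABULARY)
    pattern_names = sorted(PATTERN_VOCABULARY)
    for obs in observer_ids:
        for sp in truth.species_ids:
            cols = set(truth.colours[sp])
            for c in colour_names:
                if rng.uniform() < rate:
                    cols.symmetric_difference_update({c})
            while len(cols) > MAX_SALIENT_COLOURS:
                cols.remove(sorted(cols)[rng.integers(len(cols))])
            pats = set(truth.patterns[sp])
            for p in pattern_names:
                if rng.uniform() < rate:
                    pats.symmetric_difference_update({p})
            out.append(
                ObserverScore(
                    species_id=sp,
                    observer_id=obs,
                    colours=frozenset(cols),
                    patterns=frozenset(pats),
                )
            )
    return out


# ---------------------------------------------------------------------------
# Full synthetic datasets
# ---------------------------------------------------------------------------


@dataclass
class SyntheticDataset:
    """One complete simulated study with its latent truth."""

    tree: dendropy.Tree
    dist: PatristicDistances
    scores: list[ObserverScore]
    ecology: list[EcologyRecord]
    truth: dict = field(default_factory=dict)


def simulate_dataset(
    config: SimConfig,
    planted_colour: str = "orange",
    n_null_colours: int = 3,
    n_null_patterns: int = 2,
    null_beta0: float = -1.0,
) -> SyntheticDataset:
    """Simulate a pipeline-ready dataset with one planted association.

    The predictor is forb-feeding (species not in the predictor clade/state
    feed on woody hosts); the planted response is ``planted_colour`` with
    effect ``config.beta_true``.  ``n_null_colours`` additional colours and
    ``n_null_patterns`` patterns evolve with the same phylogenetic signal
    but zero association with the predictor.  Two observers score the
    resulting colour/pattern truth at ``config.disagreement_rate``.
    """
    master = np.random.default_rng(config.seed)
    tree = simulate_tree(config)
    dist = patristic_matrix(tree, normalize=True)
    species = list(dist.labels)
    n = len(species)

    x = simulate_predictor(tree, config, rng=master)
    y_planted = simulate_response(dist, x, config, rng=master)

    null_cfg = SimConfig(**{**config.to_dict(), "beta_true": (null_beta0, 0.0)})
    pool_colours = [c for c in sorted(COLOUR_VOCABULARY) if c != planted_colour]
    null_colours = pool_colours[:n_null_colours]
    null_patterns = sorted(PATTERN_VOCABULARY)[:n_null_patterns]

    colour_traits = {planted_colour: y_planted}
    for c in null_colours:
        colour_traits[c] = simulate_response(dist, np.zeros(n), null_cfg, rng=master)
    pattern_traits = {}
    for p in null_patterns:
        pattern_traits[p] = simulate_response(dist, np.zeros(n), null_cfg, rng=master)

    colours = {}
    patterns = {}
    for i, sp in enumerate(species):
        cset = {c for c, v in colour_traits.items() if v[i]}
        while len(cset) > MAX_SALIENT_COLOURS:
            cset.remove(sorted(cset)[master.integers(len(cset))])
        colours[sp] = frozenset(cset)
        patterns[sp] = frozenset(p for p, v in pattern_traits.items() if v[i])
    truth_scores = TrueScores(species_ids=species, colours=colours, patterns=patterns)
    scores = simulate_observers(truth_scores, config, rng=master)

    diets = ("monophagous", "oligophagous", "polyphagous")
    ecology = [
        EcologyRecord(
            species_id=sp,
            diet_breadth=diets[master.integers(3)],
            tissue="leaves",
            growth_forms=frozenset({"forb"} if x[i] else {"woody"}),
        )
        for i, sp in enumerate(species)
    ]
    truth = {
        "config": config.to_dict(),
        "planted_response": planted_colour,
        "planted_predictor": "forb",
        "beta_true": list(config.beta_true),
        "null_colours": null_colours,
        "null_patterns": null_patterns,
        "predictor_states": [int(v) for v in x],
    }
    return SyntheticDataset(tree=tree, dist=dist, scores=scores, ecology=ecology, truth=truth)
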