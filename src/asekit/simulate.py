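"""Synthetic fossil trees and hierarchical character data.

Everything the analysis consumes can be generated here: birth--death time
trees with extinct (fossil) and extant tips, FAD/LAD age ranges around the
true tip ages, forward-simulated character histories under any rate matrix,
and a "feather-like" 6-state data set whose complex states cluster
phylogenetically (simulated under an ordered low-rate chain model, the
statistical signature of the empirical character this package was built
around). Ground-truth node states are returned for recovery scoring.

All randomness flows from a single seed recorded in the outputs; generators
never touch global random state.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import dendropy
import numpy as np

from .models import (
    FEATHER_STATES_2,
    FEATHER_STATES_3,
    FEATHER_STATES_6,
    build_q,
    mk_template,
)
from .trees import TaxonAges, TimeTree

__all__ = [
    "SimConfig",
    "simulate_time_tree",
    "simulate_history",
    "make_feather_like_dataset",
    "recode",
    "fixture_dataset",
]


class SimulationError(RuntimeError):
    pass


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic data set.

    Defaults emulate the empirical setting: a ~100-tip fossil tree spanning
    roughly 160 myr, a slowly evolving 6-state ordered character starting
    from the simplest state, and a small fraction of ambiguously coded tips.
    FAD/LAD half-widths are drawn uniformly on [0, 5] myr around the true tip
    age, wide enough to exercise zero-length-branch handling in the
    time-scalers.
    """

    n_tips: int = 94
    birth_rate: float = 0.06  # lineages / myr
    death_rate: float = 0.04
    age_span: float = 160.0  # Ma; age of the root
    rate: float = 0.02  # events / myr of the true ordered model
    scheme: str = "ER"
    ordered: bool = True
    n_states: int = 6
    root_state: int = 0
    ambiguity_fraction: float = 0.05
    unknown_fraction: float = 0.0
    fad_lad_halfwidth: float = 5.0
    n_outgroup: int = 3
    seed: int = 0


# ---------------------------------------------------------------------------
# birth-death time trees with fossil tips
# ---------------------------------------------------------------------------


def simulate_time_tree(config: SimConfig) -> tuple[TimeTree, TaxonAges]:
    """Forward birth--death simulation kept until ``n_tips`` total tips exist.

    Lineages split at ``birth_rate`` and die at ``death_rate``; the process
    starts at ``age_span`` Ma and runs toward the present. Extinct lineages
    become fossil tips dated at their extinction age; survivors become tips at
    age 0. FAD/LAD ranges are drawn around the true tip ages (FAD older,
    LAD younger, floored at 0), so re-dating the topology from the ages table
    exercises the time-scaling machinery, zero-length branches included.
    Degenerate runs (total extinction before reaching ``n_tips``) are retried
    up to 200 times with fresh substreams of the same seed.
    """
    if config.n_tips < 3:
        raise SimulationError("need at least 3 tips")
    rng = np.random.default_rng(config.seed)
    for _attempt in range(200):
        result = _one_birth_death(config, rng)
        if result is not None:
            return result
    raise SimulationError(
        "birth-death simulation failed 200 times; rates too extinction-prone"
    )


def _one_birth_death(config: SimConfig, rng: np.random.Generator):
    taxon_ns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxon_ns)
    root = tree.seed_node
    root.age = float(config.age_span)
    alive = [root]
    fossils: list[tuple[dendropy.Node, float]] = []
    t = float(config.age_span)
    total_rate_per_lineage = config.birth_rate + config.death_rate

    def n_tips_now() -> int:
        return len(alive) + len(fossils)

    while t > 0 and alive and n_tips_now() < config.n_tips:
        k = len(alive)
        t -= rng.exponential(1.0 / (k * total_rate_per_lineage))
        if t <= 0:
            break
        node = alive[rng.integers(k)]
        if rng.random() < config.birth_rate / total_rate_per_lineage:
            node.age = t
            for _ in range(2):
                child = dendropy.Node()
                node.add_child(child)
                alive.append(child)
            alive.remove(node)
        else:
            node.age = t
            alive.remove(node)
            fossils.append((node, t))
    if n_tips_now() < config.n_tips or not alive:
        return None
    # survivors at the stopping time become extant tips; shift the time axis
    # so that the stopping moment is the present (age 0)
    present = max(t, 0.0)
    for node in alive:
        node.age = present
    if present > 0:
        for node in tree.preorder_node_iter():
            node.age = max(node.age - present, 0.0)
    # name the tips and build the age table
    fad, lad = {}, {}
    for i, leaf in enumerate(tree.leaf_node_iter()):
        label = f"t{i + 1}"
        leaf.taxon = taxon_ns.new_taxon(label=label)
        true_age = float(leaf.age)
        w_older = rng.uniform(0.0, config.fad_lad_halfwidth)
        w_younger = rng.uniform(0.0, config.fad_lad_halfwidth)
        fad[label] = true_age + w_older
        lad[label] = max(true_age - w_younger, 0.0)
        if true_age <= 0.0:  # extant tip
            fad[label], lad[label] = max(true_age, 0.0), 0.0
    for node in tree.preorder_node_iter():
        parent = node.parent_node
        node.edge.length = (0.0 if parent is None else parent.age - node.age)
    tt = TimeTree(tree, root_length=0.0)
    return tt, TaxonAges(fad=fad, lad=lad)


# ---------------------------------------------------------------------------
# character histories
# ---------------------------------------------------------------------------


def simulate_history(
    tt: TimeTree,
    q: np.ndarray,
    root_state: int = 0,
    seed: int = 0,
) -> tuple[dict, dict]:
    """Continuous-time Markov simulation of one character along the tree.

    Exponential waiting times with the current state's exit rate; jump
    probabilities proportional to the off-diagonal row of ``q``. Returns
    (tip states, internal-node states) keyed by node label, as state indices
    into the generator's state space.
    """
    q = np.asarray(q, dtype=float)
    rng = np.random.default_rng(seed)
    n = q.shape[0]
    states: dict[int, int] = {id(tt.root): int(root_state)}
    tips, nodes = {}, {}
    for node in tt.tree.preorder_node_iter():
        if node.parent_node is None:
            state = states[id(node)]
        else:
            state = states[id(node.parent_node)]
            remaining = float(node.edge.length)
            while True:
                exit_rate = -q[state, state]
                if exit_rate <= 0:
                    break
                wait = rng.exponential(1.0 / exit_rate)
                if wait >= remaining:
                    break
                remaining -= wait
                probs = np.clip(q[state], 0.0, None)
                probs[state] = 0.0
                state = int(rng.choice(n, p=probs / probs.sum()))
            states[id(node)] = state
        if node.is_leaf():
            tips[node.taxon.label] = state
        else:
            states[id(node)] = state
            nodes[node.label] = state
    return tips, nodes


# ---------------------------------------------------------------------------
# feather-like data sets
# ---------------------------------------------------------------------------


def make_feather_like_dataset(config: SimConfig = SimConfig()):
    """A complete synthetic study data set in the 6-state coding.

    Simulates a fossil time tree, evolves an ordered (or unordered) character
    from the simplest state under a low rate -- so developmentally complex
    states end up phylogenetically clustered near the most nested clades --
    marks a basal subset of tips as the outgroup, and injects ambiguity
    (``a&b`` neighbour sets) and unknown (``?``) codes at the configured
    fractions.

    Returns a dict with the tree, ages, character codes (strings), the true
    tip and node states, the outgroup taxa, and the template/rates used.
    """
    labels = {6: FEATHER_STATES_6, 3: FEATHER_STATES_3, 2: FEATHER_STATES_2}.get(
        config.n_states, tuple(str(i) for i in range(config.n_states))
    )
    template = mk_template(
        config.n_states, config.scheme, ordered=config.ordered, labels=labels
    )
    rates = np.full(template.n_params, config.rate)
    q = build_q(template, rates)
    tt, ages = simulate_time_tree(config)
    tip_states, node_states = simulate_history(
        tt, q, root_state=config.root_state, seed=config.seed + 1
    )
    rng = np.random.default_rng(config.seed + 2)
    codes: dict[str, str] = {}
    for taxon, state in tip_states.items():
        u = rng.random()
        if u < config.unknown_fraction:
            codes[taxon] = "?"
        elif u < config.unknown_fraction + config.ambiguity_fraction:
            other = state + 1 if state + 1 < config.n_states else state - 1
            pair = sorted({state, other})
            codes[taxon] = "&".join(str(s) for s in pair)
        else:
            codes[taxon] = str(state)
    outgroup = _basal_tips(tt, config.n_outgroup)
    return {
        "tree": tt,
        "ages": ages,
        "codes": codes,
        "true_tip_states": tip_states,
        "true_node_states": node_states,
        "outgroup": outgroup,
        "template": template,
        "rates": rates,
        "states": labels,
        "seed": config.seed,
    }


def _basal_tips(tt: TimeTree, n: int) -> list[str]:
    """The n tips closest to the root (fewest intervening nodes, oldest
    divergence first), playing the role of the outgroup."""
    scored = []
    for leaf in tt.tree.leaf_node_iter():
        depth = 0
        node = leaf
        while node.parent_node is not None:
            depth += 1
            node = node.parent_node
        scored.append((depth, -leaf.age if hasattr(leaf, "age") else 0.0, leaf.taxon.label))
    scored.sort()
    return [label for _, _, label in scored[:n]]


# ---------------------------------------------------------------------------
# recoding between coding strategies
# ---------------------------------------------------------------------------

# 6-state index -> coding 2 (3-state) index and coding 1 (binary) index
_RECODE_6_TO_3 = {0: 0, 1: 1, 2: 1, 3: 1, 4: 2, 5: 2}
_RECODE_6_TO_2 = {0: 0, 1: 1, 2: 1, 3: 1, 4: 1, 5: 1}


def recode(codes: Mapping[str, str], strategy: int) -> dict[str, str]:
    """Recode a 6-state character matrix to coding strategy 1, 2 or 3.

    Strategy 3 is the identity; strategy 2 collapses the three filamentous
    morphotypes and the two pennaceous ones; strategy 1 collapses every
    feather state onto 'feathers'. Ambiguity sets are recoded memberwise with
    duplicates collapsed; '?' stays unknown.
    """
    if strategy not in (1, 2, 3):
        raise SimulationError(f"unknown coding strategy: {strategy}")
    if strategy == 3:
        return dict(codes)
    mapping = _RECODE_6_TO_3 if strategy == 2 else _RECODE_6_TO_2
    out = {}
    for taxon, code in codes.items():
        code = str(code).strip()
        if code in {"?", "-", ""}:
            out[taxon] = "?"
            continue
        members = []
        for part in code.split("&"):
            s = int(part)
            if s not in mapping:
                raise SimulationError(f"unknown 6-state code {part!r}")
            if mapping[s] not in members:
                members.append(mapping[s])
        out[taxon] = "&".join(str(m) for m in sorted(members))
    return out


def coding_labels(strategy: int) -> tuple[str, ...]:
    return {1: FEATHER_STATES_2, 2: FEATHER_STATES_3, 3: FEATHER_STATES_6}[strategy]


def fixture_dataset(seed: int = 11):
    """The small canned data set used by the test suite: 12 tips, ambiguity
    present, deterministic for a given seed."""
    cfg = SimConfig(
        n_tips=12, birth_rate=0.09, death_rate=0.05, age_span=120.0,
        rate=0.02, ambiguity_fraction=0.1, n_outgroup=2, seed=seed,
    )
    return make_feather_like_dataset(cfg)
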