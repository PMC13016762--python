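"""Rate-matrix templates for Markov models of discrete character evolution.

A *template* is an integer matrix over the model's state space: entry 0 marks a
forbidden transition, and equal positive integers mark transitions that share a
rate parameter. Families provided:

* ``mk_template`` -- standard Mk (ER/SYM/ARD), unordered or ordered (chain).
* ``amalgamate_ed`` -- embedded-dependency amalgamation of a hierarchy of
  binary characters into a single character over observable states only.
  Variant QL lets a trait be born together with any of its dependent
  qualitative properties; variant BD forbids transitions implying two or more
  simultaneous trait births.
* ``amalgamate_smm`` -- structured Markov model over the full Cartesian
  product of the binary characters, retaining unobserved ("hidden liability")
  combinations; ``ind`` amalgamates the characters as independent, ``switch``
  gives a dependent character distinct rates under each state of its
  controller.
* ``expand_hrm`` -- hidden rates model: observed states duplicated across 2
  or 3 latent rate categories (slow/fast or slow/medium/fast) forming a chain.

Schemes: ER shares one rate within each parameter group, SYM shares
forward/backward rates, ARD frees every direction. For the amalgamated
families the scheme applies per component character (a binary character's ER
and SYM templates coincide).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from itertools import product
from pathlib import Path

import numpy as np

__all__ = [
    "StateSpace",
    "RateTemplate",
    "DependencyHierarchy",
    "mk_template",
    "amalgamate_ed",
    "amalgamate_smm",
    "expand_hrm",
    "build_q",
    "feather_hierarchy",
    "model_grid",
    "SCHEMES",
    "ARCHITECTURES",
]

SCHEMES = ("ER", "SYM", "ARD")
ARCHITECTURES = (
    "unordered", "ordered", "ED", "SMM-ind", "SMM-switch", "HRM-2", "HRM-3",
)


class ModelError(ValueError):
    pass


@dataclass(frozen=True)
class StateSpace:
    """Model states with a many-to-one observation map onto observed states."""

    model_states: tuple[str, ...]
    observed_states: tuple[str, ...]
    observation_map: tuple[int, ...]  # model index -> observed index

    def __post_init__(self) -> None:
        if len(self.observation_map) != len(self.model_states):
            raise ModelError("observation map must cover every model state")
        if set(self.observation_map) != set(range(len(self.observed_states))):
            raise ModelError("observation map must be surjective onto observed states")

    @classmethod
    def identity(cls, states: tuple[str, ...] | list[str]) -> "StateSpace":
        states = tuple(states)
        return cls(states, states, tuple(range(len(states))))

    @property
    def n_model(self) -> int:
        return len(self.model_states)

    @property
    def n_observed(self) -> int:
        return len(self.observed_states)

    def preimages(self, observed_index: int) -> list[int]:
        return [i for i, o in enumerate(self.observation_map) if o == observed_index]

    def collapse(self, vectors: np.ndarray) -> np.ndarray:
        """Sum model-state columns onto observed states (last axis)."""
        vectors = np.asarray(vectors)
        out = np.zeros(vectors.shape[:-1] + (self.n_observed,))
        for i, o in enumerate(self.observation_map):
            out[..., o] += vectors[..., i]
        return out

    def expand(self, observed_vectors: np.ndarray) -> np.ndarray:
        """Copy each observed value to all its hidden preimages (for tip data)."""
        observed_vectors = np.asarray(observed_vectors)
        return observed_vectors[..., list(self.observation_map)]

    def to_json(self) -> dict:
        return {
            "model_states": list(self.model_states),
            "observed_states": list(self.observed_states),
            "observation_map": list(self.observation_map),
        }


@dataclass(frozen=True)
class RateTemplate:
    """Shared-parameter index matrix defining a model family.

    ``index[i, j] == 0`` forbids i->j; equal positive integers share a rate.
    Indices form the contiguous set ``1..n_params``.
    """

    index: np.ndarray
    space: StateSpace
    scheme: str
    architecture: str

    def __post_init__(self) -> None:
        idx = np.asarray(self.index, dtype=int)
        object.__setattr__(self, "index", idx)
        if idx.shape != (self.space.n_model, self.space.n_model):
            raise ModelError("index matrix shape must match the model state count")
        if self.scheme not in SCHEMES:
            raise ModelError(f"unknown scheme {self.scheme!r}")
        off = idx[~np.eye(idx.shape[0], dtype=bool)]
        used = sorted(set(off[off > 0].tolist()))
        if used != list(range(1, len(used) + 1)):
            raise ModelError("parameter indices must be contiguous from 1")
        if self.scheme == "SYM":
            sym_ok = True
            for i in range(idx.shape[0]):
                for j in range(idx.shape[0]):
                    if i != j and idx[i, j] and idx[j, i] and idx[i, j] != idx[j, i]:
                        sym_ok = False
            if not sym_ok:
                raise ModelError("SYM template must share forward/backward indices")

    @property
    def n_states(self) -> int:
        return self.space.n_model

    @property
    def n_params(self) -> int:
        off = self.index[~np.eye(self.index.shape[0], dtype=bool)]
        return int(off.max()) if (off > 0).any() else 0

    @property
    def name(self) -> str:
        return f"{self.scheme} {self.architecture}"

    def to_json(self) -> dict:
        return {
            "architecture": self.architecture,
            "scheme": self.scheme,
            "n_params": self.n_params,
            "index": self.index.tolist(),
            "space": self.space.to_json(),
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_json(), indent=1))


def _renumber(index: np.ndarray) -> np.ndarray:
    """Compress positive entries to the contiguous range 1..k, row-major order."""
    out = np.zeros_like(index)
    mapping: dict[int, int] = {}
    n = index.shape[0]
    for i in range(n):
        for j in range(n):
            if i != j and index[i, j] > 0:
                key = int(index[i, j])
                if key not in mapping:
                    mapping[key] = len(mapping) + 1
                out[i, j] = mapping[key]
    return out


def _apply_scheme(allowed: np.ndarray, scheme: str) -> np.ndarray:
    """Index an allowed-transition mask under ER/SYM/ARD sharing."""
    n = allowed.shape[0]
    index = np.zeros((n, n), dtype=int)
    counter = 0
    for i in range(n):
        for j in range(n):
            if i == j or not allowed[i, j]:
                continue
            if scheme == "ER":
                index[i, j] = 1
            elif scheme == "SYM":
                if allowed[j, i] and index[j, i] > 0:
                    index[i, j] = index[j, i]
                else:
                    counter += 1
                    index[i, j] = counter
            else:  # ARD
                counter += 1
                index[i, j] = counter
    return _renumber(index)


# ---------------------------------------------------------------------------
# standard Mk
# ---------------------------------------------------------------------------


def mk_template(
    n_states: int,
    scheme: str = "ER",
    ordered: bool = False,
    labels: tuple[str, ...] | None = None,
) -> RateTemplate:
    """Standard Mk template: all transitions (unordered) or chain-adjacent
    transitions (ordered) under ER/SYM/ARD sharing."""
    if n_states < 2:
        raise ModelError("an Mk model needs at least 2 states")
    if scheme not in SCHEMES:
        raise ModelError(f"unknown scheme {scheme!r}")
    if labels is None:
        labels = tuple(str(i) for i in range(n_states))
    allowed = ~np.eye(n_states, dtype=bool)
    if ordered:
        adj = np.zeros((n_states, n_states), dtype=bool)
        for i in range(n_states - 1):
            adj[i, i + 1] = adj[i + 1, i] = True
        allowed &= adj
    return RateTemplate(
        index=_apply_scheme(allowed, scheme),
        space=StateSpace.identity(labels),
        scheme=scheme,
        architecture="ordered" if ordered else "unordered",
    )


# ---------------------------------------------------------------------------
# dependency hierarchies
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DependencyHierarchy:
    """Binary characters with applicability dependencies.

    ``parents[i]`` is the index of the character controlling character ``i``
    (None for the single root character); a dependent character is applicable
    only when its controller is in state 1. The feather codings use a chain:
    each character controls the next.
    """

    characters: tuple[str, ...]
    parents: tuple[int | None, ...]

    def __post_init__(self) -> None:
        m = len(self.characters)
        if len(self.parents) != m:
            raise ModelError("one parent entry per character required")
        roots = [i for i, p in enumerate(self.parents) if p is None]
        if len(roots) != 1:
            raise ModelError("exactly one root controlling character required")
        # acyclicity: walking parents from any character must reach the root
        for i in range(m):
            seen, j = set(), i
            while self.parents[j] is not None:
                if j in seen:
                    raise ModelError("cyclic dependency hierarchy")
                seen.add(j)
                j = self.parents[j]

    @classmethod
    def chain(cls, characters: tuple[str, ...] | list[str]) -> "DependencyHierarchy":
        characters = tuple(characters)
        parents: tuple[int | None, ...] = (None,) + tuple(range(len(characters) - 1))
        return cls(characters, parents)

    @property
    def is_chain(self) -> bool:
        return self.parents == (None,) + tuple(range(len(self.characters) - 1))

    def __len__(self) -> int:
        return len(self.characters)


def feather_hierarchy(coding: int = 3) -> DependencyHierarchy:
    """The nested feather-complexity hierarchy for coding strategies 2 and 3."""
    if coding == 2:
        return DependencyHierarchy.chain(("feathers", "pennaceous"))
    if coding == 3:
        return DependencyHierarchy.chain(
            ("feathers", "basally_joined", "central_filament", "pennaceous",
             "asymmetrical")
        )
    raise ModelError("dependency hierarchies exist for codings 2 and 3 only")


FEATHER_STATES_6 = (
    "scales", "monofilament", "basally_joined", "central_filament",
    "pennaceous", "asymmetrical",
)
FEATHER_STATES_3 = ("scales", "filamentous", "pennaceous")
FEATHER_STATES_2 = ("scales", "feathers")


def _chain_observed_labels(hierarchy: DependencyHierarchy) -> tuple[str, ...]:
    m = len(hierarchy)
    if m == 2 and hierarchy.characters == ("feathers", "pennaceous"):
        return FEATHER_STATES_3
    if m == 5:
        return FEATHER_STATES_6
    return ("absent",) + tuple(
        f"level{i + 1}" for i in range(m)
    )


# ---------------------------------------------------------------------------
# embedded dependency (ED)
# ---------------------------------------------------------------------------


def amalgamate_ed(
    hierarchy: DependencyHierarchy,
    scheme: str = "ER",
    variant: str = "QL",
) -> tuple[StateSpace, RateTemplate]:
    """Amalgamate a chain hierarchy into a single observable-state character.

    States are the complexity levels 0..m (level j = the first j characters
    present). Every transition corresponds to one underlying character event
    and inherits that event's parameter:

    * gain of character j+1 drives any upward move from level j (QL: to any
      higher level, since dependent qualitative properties are born with the
      trait; BD: to level j+1 only -- two or more births are forbidden);
    * loss of character j'+1 drives any move down to level j' (allowed in
      both variants: the deeper characters become inapplicable, not "dead").

    ER shares gain and loss within a character; SYM likewise (binary
    characters make them coincide); ARD frees gain from loss.
    """
    if variant not in {"QL", "BD"}:
        raise ModelError(f"unknown ED variant {variant!r}")
    if scheme not in SCHEMES:
        raise ModelError(f"unknown scheme {scheme!r}")
    if not hierarchy.is_chain:
        raise ModelError("ED amalgamation implemented for chain hierarchies")
    m = len(hierarchy)
    labels = _chain_observed_labels(hierarchy)
    n = m + 1
    index = np.zeros((n, n), dtype=int)

    def param(char: int, event: str) -> int:
        # parameter id for (character, gain|loss) before renumbering
        if scheme == "ER" or scheme == "SYM":
            return char + 1
        return 2 * char + (1 if event == "gain" else 2)

    for j in range(n):
        for jp in range(n):
            if j == jp:
                continue
            if jp > j:  # upward: driven by gain of character j+1 (index j)
                if variant == "BD" and jp - j > 1:
                    continue
                index[j, jp] = param(j, "gain")
            else:  # downward to level jp: loss of character jp+1 (index jp)
                index[j, jp] = param(jp, "loss")
    space = StateSpace.identity(labels[:n])
    return space, RateTemplate(
        index=_renumber(index),
        space=space,
        scheme=scheme,
        architecture=f"ED-{variant}",
    )


# ---------------------------------------------------------------------------
# structured Markov models (SMM)
# ---------------------------------------------------------------------------


def _observed_level(bits: tuple[int, ...], hierarchy: DependencyHierarchy) -> int:
    """Deepest applicable-and-present level of a full character assignment."""
    level = 0
    for i, p in enumerate(hierarchy.parents):
        applicable = p is None or (bits[p] == 1 and _is_on_path(bits, hierarchy, p))
        if applicable and bits[i] == 1:
            level = max(level, _depth(hierarchy, i) + 1)
    return level


def _depth(hierarchy: DependencyHierarchy, i: int) -> int:
    d, j = 0, i
    while hierarchy.parents[j] is not None:
        d += 1
        j = hierarchy.parents[j]
    return d


def _is_on_path(bits: tuple[int, ...], hierarchy: DependencyHierarchy, i: int) -> bool:
    j = i
    while j is not None:
        if bits[j] == 0:
            return False
        j = hierarchy.parents[j]
    return True


def amalgamate_smm(
    hierarchy: DependencyHierarchy,
    scheme: str = "ER",
    variant: str = "ind",
) -> tuple[StateSpace, RateTemplate]:
    """Structured Markov model over the full product of the binary characters.

    Model states are all 2^m bit vectors (unobserved combinations retained as
    hidden liabilities); the observation map sends a vector to the deepest
    level whose whole controlling path is present. Only one character may
    change at a time. ``ind``: a character's rates ignore the rest of the
    system; ``switch``: a dependent character's rates take distinct parameters
    under each state of its controller.
    """
    if variant not in {"ind", "switch"}:
        raise ModelError(f"unknown SMM variant {variant!r}")
    if scheme not in SCHEMES:
        raise ModelError(f"unknown scheme {scheme!r}")
    m = len(hierarchy)
    states = list(product((0, 1), repeat=m))
    model_labels = tuple("".join(map(str, s)) for s in states)
    if hierarchy.is_chain:
        observed_labels = _chain_observed_labels(hierarchy)
    else:
        observed_labels = tuple(
            f"level{l}" for l in range(max(_depth(hierarchy, i) for i in range(m)) + 2)
        )
    obs_map = tuple(
        (lambda bits: sum(1 for _ in _leading(bits)) if hierarchy.is_chain
         else _observed_level(bits, hierarchy))(s)
        for s in states
    )

    n = len(states)
    index = np.zeros((n, n), dtype=int)
    for a, sa in enumerate(states):
        for b, sb in enumerate(states):
            diff = [i for i in range(m) if sa[i] != sb[i]]
            if len(diff) != 1:
                continue  # identity or a forbidden simultaneous change
            char = diff[0]
            event = "gain" if sb[char] == 1 else "loss"
            ctrl = hierarchy.parents[char]
            ctx = 0 if (variant == "ind" or ctrl is None) else sa[ctrl]
            if scheme in ("ER", "SYM"):
                index[a, b] = 1 + 2 * char + ctx
            else:  # ARD
                index[a, b] = 1 + 4 * char + 2 * ctx + (0 if event == "gain" else 1)
    space = StateSpace(model_labels, observed_labels, obs_map)
    return space, RateTemplate(
        index=_renumber(index),
        space=space,
        scheme=scheme,
        architecture=f"SMM-{variant}",
    )


def _leading(bits: tuple[int, ...]):
    for b in bits:
        if b == 1:
            yield b
        else:
            return


# ---------------------------------------------------------------------------
# hidden rates model (HRM)
# ---------------------------------------------------------------------------


def expand_hrm(
    base: RateTemplate,
    n_categories: int = 2,
    scheme: str | None = None,
) -> tuple[StateSpace, RateTemplate]:
    """Duplicate a base template's observed states across latent rate
    categories.

    Within each category the base support is re-indexed with category-specific
    parameters (so "slow" and "fast" copies of the process differ). Category
    switches are allowed only without a simultaneous observed-state change and
    only between adjacent categories (slow <-> medium <-> fast); ER/SYM share
    one switch parameter per adjacent pair, ARD frees the two directions.
    """
    if n_categories not in (2, 3):
        raise ModelError("HRM supports 2 or 3 rate categories")
    scheme = scheme or base.scheme
    if scheme not in SCHEMES:
        raise ModelError(f"unknown scheme {scheme!r}")
    if base.space.n_model != base.space.n_observed:
        raise ModelError("HRM expansion expects an observed-state base template")
    k = base.space.n_observed
    obs = base.space.observed_states
    allowed = base.index > 0
    model_labels = tuple(
        f"{s}|R{c + 1}" for c in range(n_categories) for s in obs
    )
    obs_map = tuple(i for _ in range(n_categories) for i in range(k))
    n = k * n_categories
    index = np.zeros((n, n), dtype=int)
    offset = 0
    for c in range(n_categories):
        sub = _apply_scheme(allowed, scheme)
        nz = sub > 0
        sub[nz] += offset
        offset += int(sub.max()) if nz.any() else 0
        index[c * k:(c + 1) * k, c * k:(c + 1) * k] = sub
    for c in range(n_categories - 1):
        if scheme == "ARD":
            up, down = offset + 1, offset + 2
            offset += 2
        else:
            up = down = offset + 1
            offset += 1
        for i in range(k):
            index[c * k + i, (c + 1) * k + i] = up
            index[(c + 1) * k + i, c * k + i] = down
    space = StateSpace(model_labels, obs, obs_map)
    return space, RateTemplate(
        index=_renumber(index),
        space=space,
        scheme=scheme,
        architecture=f"HRM-{n_categories}",
    )


# ---------------------------------------------------------------------------
# generator instantiation
# ---------------------------------------------------------------------------


def build_q(template: RateTemplate, rates) -> np.ndarray:
    """Instantiate the Markov generator: off-diagonal entries take the
    assigned rates (0 where forbidden), diagonals make rows sum to zero."""
    rates = np.asarray(rates, dtype=float)
    if rates.shape != (template.n_params,):
        raise ModelError(
            f"expected {template.n_params} rates, got {rates.shape}"
        )
    if np.any(rates <= 0):
        raise ModelError("all rates must be positive")
    lookup = np.concatenate([[0.0], rates])
    q = lookup[template.index]
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    return q


# ---------------------------------------------------------------------------
# the experiment model grid
# ---------------------------------------------------------------------------


def model_grid(
    n_states: int = 6,
    hierarchy: DependencyHierarchy | None = None,
    ed_variant: str = "QL",
    architectures: tuple[str, ...] = ARCHITECTURES,
    schemes: tuple[str, ...] = SCHEMES,
) -> dict[str, RateTemplate]:
    """Enumerate the model grid: architectures x schemes on one coding.

    The full default grid on the 6-state coding is the 21-model set
    {unordered, ordered, ED, SMM-ind, SMM-switch, HRM-2, HRM-3} x
    {ER, SYM, ARD}.
    """
    if hierarchy is None:
        hierarchy = feather_hierarchy(3 if n_states == 6 else 2)
    labels = (
        FEATHER_STATES_6 if n_states == 6
        else FEATHER_STATES_3 if n_states == 3
        else tuple(str(i) for i in range(n_states))
    )
    grid: dict[str, RateTemplate] = {}
    for arch in architectures:
        for scheme in schemes:
            if arch == "unordered":
                t = mk_template(n_states, scheme, ordered=False, labels=labels)
            elif arch == "ordered":
                t = mk_template(n_states, scheme, ordered=True, labels=labels)
            elif arch == "ED":
                _, t = amalgamate_ed(hierarchy, scheme, variant=ed_variant)
            elif arch == "SMM-ind":
                _, t = amalgamate_smm(hierarchy, scheme, variant="ind")
            elif arch == "SMM-switch":
                _, t = amalgamate_smm(hierarchy, scheme, variant="switch")
            elif arch == "HRM-2":
                _, t = expand_hrm(mk_template(n_states, scheme, labels=labels), 2, scheme)
            elif arch == "HRM-3":
                _, t = expand_hrm(mk_template(n_states, scheme, labels=labels), 3, scheme)
            else:
                raise ModelError(f"unknown architecture {arch!r}")
            grid[f"{arch} {scheme}"] = t
    return grid
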