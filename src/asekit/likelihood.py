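"""Pruning likelihoods, maximum-likelihood fitting, and marginal ancestral
state estimation on time trees.

The likelihood of a discrete character under a continuous-time Markov model
is computed by Felsenstein's pruning algorithm with per-branch transition
matrices ``expm(Q*t)``. Partial likelihood vectors are rescaled at every node
(accumulating log factors) so that 32-state models on branches spanning
0.1--100 myr stay in range. Transition matrices for all branches are obtained
from one eigendecomposition of ``Q`` when it is well conditioned, falling back
to scaling-and-squaring ``expm`` per branch otherwise.

Marginal ancestral estimates use the standard two-pass scheme: the marginal
at a node is proportional to the product of the partial likelihoods flowing
into it from every direction, times the root-prior contribution. Hidden
states (SMM liabilities, HRM rate categories) are collapsed onto observed
states by summation for reporting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.linalg import expm
from scipy.optimize import minimize

from .models import RateTemplate, StateSpace, build_q
from .trees import TimeTree

__all__ = [
    "TipData",
    "FitOptions",
    "FitResult",
    "MarginalTable",
    "encode_tips",
    "prune_loglik",
    "fit_model",
    "marginal_ancestral",
    "aggregate_states",
]

ROOT_PRIORS = ("flat", "stationary", "fitzjohn")


class LikelihoodError(ValueError):
    pass


# ---------------------------------------------------------------------------
# tip data
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TipData:
    """Per-tip likelihood vectors over *observed* states.

    A row holds 1 for every state compatible with the observation and 0
    elsewhere; an all-ones row is an unknown ('?'). Rows are keyed by taxon.
    """

    taxa: tuple[str, ...]
    matrix: np.ndarray  # (n_taxa, n_observed) of 0/1
    space: StateSpace

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        object.__setattr__(self, "matrix", m)
        if m.shape != (len(self.taxa), self.space.n_observed):
            raise LikelihoodError("tip matrix shape mismatch")
        if not (m.sum(axis=1) >= 1).all():
            bad = self.taxa[int(np.argmin(m.sum(axis=1)))]
            raise LikelihoodError(f"tip {bad!r} compatible with no state")

    def row(self, taxon: str) -> np.ndarray:
        return self.matrix[self.taxa.index(taxon)]

    def model_vectors(self) -> dict[str, np.ndarray]:
        """Vectors over model states (observed values copied to preimages)."""
        expanded = self.space.expand(self.matrix)
        return {t: expanded[i] for i, t in enumerate(self.taxa)}

    def with_unknown(self, taxon: str) -> "TipData":
        m = self.matrix.copy()
        m[self.taxa.index(taxon)] = 1.0
        return TipData(self.taxa, m, self.space)

    def without(self, taxon: str) -> "TipData":
        keep = [i for i, t in enumerate(self.taxa) if t != taxon]
        return TipData(
            tuple(self.taxa[i] for i in keep), self.matrix[keep], self.space
        )

    def true_observed_set(self, taxon: str) -> list[int]:
        """Indices of the observed states compatible with the recorded coding."""
        return [int(i) for i in np.flatnonzero(self.row(taxon) > 0)]


def encode_tips(
    codes: Mapping[str, str],
    space: StateSpace,
    tree_taxa: Sequence[str] | None = None,
) -> TipData:
    """Encode raw state codes into tip likelihood vectors.

    Codes name observed states by label or by index; ambiguity sets use
    ``&`` (``"0&1"``) and ``?`` (or ``-``) marks a fully unknown tip, which is
    assigned equal footing for every observed state.
    """
    label_to_idx = {s: i for i, s in enumerate(space.observed_states)}
    label_to_idx.update({str(i): i for i in range(space.n_observed)})
    taxa = tuple(codes)
    if tree_taxa is not None:
        missing = set(taxa) - set(tree_taxa)
        extra = set(tree_taxa) - set(taxa)
        if missing:
            raise LikelihoodError(f"taxa absent from tree: {sorted(missing)}")
        if extra:
            raise LikelihoodError(f"tips lacking character codes: {sorted(extra)}")
    matrix = np.zeros((len(taxa), space.n_observed))
    for r, taxon in enumerate(taxa):
        code = str(codes[taxon]).strip()
        if code in {"?", "-", ""}:
            matrix[r, :] = 1.0
            continue
        for part in code.split("&"):
            part = part.strip()
            if part not in label_to_idx:
                raise LikelihoodError(
                    f"unknown state code {part!r} for taxon {taxon!r}"
                )
            matrix[r, label_to_idx[part]] = 1.0
    return TipData(taxa, matrix, space)


# ---------------------------------------------------------------------------
# transition matrices and pruning
# ---------------------------------------------------------------------------


class _PruneContext:
    """Tree and tip data flattened to postorder arrays, built once per fit.

    ``children[i]`` lists ``(child_position, edge_index)`` pairs; edge lengths
    are gathered in one array so all transition matrices come from a single
    batched exponential per likelihood evaluation.
    """

    def __init__(self, tt: TimeTree, tips: TipData):
        self.nodes = list(tt.tree.postorder_node_iter())
        pos = {id(n): i for i, n in enumerate(self.nodes)}
        self.children: list[list[tuple[int, int]]] = []
        lengths: list[float] = []
        tipvecs = tips.model_vectors()
        self.n_model = tips.space.n_model
        self.tipmat = np.zeros((len(self.nodes), self.n_model))
        for i, node in enumerate(self.nodes):
            ch = []
            for c in node.child_nodes():
                ch.append((pos[id(c)], len(lengths)))
                lengths.append(max(float(c.edge.length), 0.0))
            self.children.append(ch)
            if node.is_leaf():
                taxon = node.taxon.label
                if taxon not in tipvecs:
                    raise LikelihoodError(f"tip {taxon!r} lacks character data")
                self.tipmat[i] = tipvecs[taxon]
        self.lengths = np.asarray(lengths)
        self.space = tips.space

    def partials(self, q: np.ndarray):
        """Scaled postorder partials, total log scale, and the P matrices."""
        ps = transition_matrices(q, self.lengths)
        part = np.empty((len(self.nodes), self.n_model))
        log_scale = 0.0
        for i, ch in enumerate(self.children):
            if not ch:
                part[i] = self.tipmat[i]
                continue
            acc = np.ones(self.n_model)
            for ci, ei in ch:
                acc = acc * (ps[ei] @ part[ci])
            top = acc.max()
            if top <= 0 or not np.isfinite(top):
                raise LikelihoodError("partial likelihoods vanished (non-finite lnL)")
            part[i] = acc / top
            log_scale += math.log(top)
        return part, log_scale, ps

    def loglik(self, q: np.ndarray, root_prior) -> float:
        part, log_scale, _ = self.partials(q)
        pi = _root_prior_vector(root_prior, part[-1], q)
        lik = float(pi @ part[-1])
        if lik <= 0 or not np.isfinite(lik):
            raise LikelihoodError("non-finite likelihood")
        return math.log(lik) + log_scale


def transition_matrices(q: np.ndarray, lengths: np.ndarray) -> np.ndarray:
    """``expm(q * t)`` for a batch of branch lengths.

    Uses one eigendecomposition of ``q`` for the whole batch; falls back to
    per-branch scaling-and-squaring when ``q`` is defective or the
    reconstruction is inaccurate.
    """
    q = np.asarray(q, dtype=float)
    lengths = np.asarray(lengths, dtype=float)
    try:
        if np.allclose(q, q.T, atol=1e-12):  # reversible-symmetric: real path
            lam, vec = np.linalg.eigh(q)
            vinv = vec.T
        else:
            lam, vec = np.linalg.eig(q)
            vinv = np.linalg.inv(vec)
            # a defective/ill-conditioned eigenbasis makes V e^{lam t} V^-1
            # unreliable; fall back to scaling-and-squaring in that case
            cond = np.linalg.norm(vec, 1) * np.linalg.norm(vinv, 1)
            if cond > 1e8:
                raise np.linalg.LinAlgError("ill-conditioned eigenbasis")
        explam = np.exp(np.multiply.outer(lengths, lam))  # (T, n)
        ps = (vec[None, :, :] * explam[:, None, :]) @ vinv
        ps = np.ascontiguousarray(ps.real)
    except np.linalg.LinAlgError:
        ps = np.stack([expm(q * t) for t in lengths])
    np.clip(ps, 0.0, None, out=ps)
    ps /= ps.sum(axis=2, keepdims=True)
    return ps


def _postorder_partials(tt: TimeTree, q: np.ndarray, tips: TipData):
    """Convenience wrapper: context plus its partials for one evaluation."""
    ctx = _PruneContext(tt, tips)
    part, log_scale, ps = ctx.partials(q)
    return ctx, part, log_scale, ps


def _root_prior_vector(prior, root_partial: np.ndarray, q: np.ndarray) -> np.ndarray:
    n = root_partial.shape[0]
    if isinstance(prior, np.ndarray) or isinstance(prior, (list, tuple)):
        pi = np.asarray(prior, dtype=float)
        if pi.shape != (n,) or pi.sum() <= 0:
            raise LikelihoodError("invalid explicit root prior")
        return pi / pi.sum()
    if prior == "flat":
        return np.full(n, 1.0 / n)
    if prior == "stationary":
        # left null vector of Q, clipped and renormalized
        vals, vecs = np.linalg.eig(q.T)
        k = int(np.argmin(np.abs(vals)))
        pi = np.clip(vecs[:, k].real, 0.0, None)
        if pi.sum() <= 0:
            raise LikelihoodError("no stationary distribution for this generator")
        return pi / pi.sum()
    if prior == "fitzjohn":
        s = root_partial.sum()
        if s <= 0:
            raise LikelihoodError("non-finite likelihood at root")
        return root_partial / s
    raise LikelihoodError(f"unknown root prior {prior!r}")


def prune_loglik(
    tt: TimeTree,
    q: np.ndarray,
    tips: TipData,
    root_prior="flat",
) -> float:
    """Felsenstein-pruning log-likelihood (nats) of the tip data under ``q``."""
    return _PruneContext(tt, tips).loglik(q, root_prior)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FitOptions:
    """Optimizer settings for maximum-likelihood rate estimation.

    Rates are optimized on the log scale within ``bounds`` (events/myr);
    ``n_starts`` local searches run from log-uniform draws of a generator
    seeded with ``seed`` (plus any explicit ``init`` first), keeping the best.
    """

    n_starts: int = 10
    seed: int = 7
    bounds: tuple[float, float] = (1e-9, 100.0)
    maxiter: int = 200
    root_prior: str = "flat"
    init: tuple[float, ...] | None = None


@dataclass(frozen=True)
class FitResult:
    """Maximum-likelihood fit of one template on one tree."""

    template: RateTemplate
    rates: np.ndarray
    loglik: float
    n_params: int
    n_tips: int
    converged: bool
    n_starts: int
    seed: int

    @property
    def aic(self) -> float:
        return -2.0 * self.loglik + 2.0 * self.n_params

    @property
    def aicc(self) -> float | None:
        """Small-sample corrected AIC; None when n - k - 1 <= 0."""
        n, k = self.n_tips, self.n_params
        if n - k - 1 <= 0:
            return None
        return self.aic + 2.0 * k * (k + 1) / (n - k - 1)

    def q(self) -> np.ndarray:
        return build_q(self.template, self.rates)


def fit_model(
    tt: TimeTree,
    template: RateTemplate,
    tips: TipData,
    options: FitOptions = FitOptions(),
) -> FitResult:
    """Fit template rates by bounded multi-start maximum likelihood.

    Deterministic given ``options.seed``. Raises if every start fails to
    produce a finite likelihood.
    """
    k = template.n_params
    lo, hi = math.log(options.bounds[0]), math.log(options.bounds[1])
    rng = np.random.default_rng(options.seed)
    ctx = _PruneContext(tt, tips)

    def neg_loglik(logrates: np.ndarray) -> float:
        try:
            return -ctx.loglik(
                build_q(template, np.exp(logrates)), options.root_prior
            )
        except (LikelihoodError, FloatingPointError):
            return 1e12

    starts = []
    if options.init is not None:
        init = np.asarray(options.init, dtype=float)
        if init.shape != (k,):
            raise LikelihoodError("init must supply one rate per parameter")
        starts.append(np.clip(np.log(init), lo, hi))
    # heuristic start: about one expected change across the tree depth
    depth = max(tt.node_ages().values()) - min(tt.node_ages().values())
    starts.append(np.full(k, np.clip(math.log(1.0 / max(depth, 1e-6)), lo, hi)))
    while len(starts) < max(options.n_starts, 1):
        starts.append(rng.uniform(math.log(1e-4), math.log(10.0), size=k))

    best, best_val, any_ok = None, np.inf, False
    for x0 in starts:
        res = minimize(
            neg_loglik,
            x0,
            method="L-BFGS-B",
            bounds=[(lo, hi)] * k,
            options={
                "maxiter": options.maxiter,
                "maxfun": options.maxiter * (k + 2),
            },
        )
        if np.isfinite(res.fun) and res.fun < 1e11:
            any_ok = True
            if res.fun < best_val:
                best, best_val = res, res.fun
    if not any_ok:
        raise LikelihoodError("optimizer failed to converge from every start")
    return FitResult(
        template=template,
        rates=np.exp(best.x),
        loglik=-best_val,
        n_params=k,
        n_tips=len(tips.taxa),
        converged=bool(best.success),
        n_starts=len(starts),
        seed=options.seed,
    )


# ---------------------------------------------------------------------------
# marginal ancestral estimation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MarginalTable:
    """Per-node marginal probabilities over observed states."""

    node_ids: tuple[str, ...]
    probs: np.ndarray  # (n_nodes, n_observed)
    states: tuple[str, ...]
    is_tip: tuple[bool, ...]
    ages: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        object.__setattr__(self, "probs", p)
        if not np.allclose(p.sum(axis=1), 1.0, atol=1e-6):
            raise LikelihoodError("marginal rows must sum to 1")

    def internal(self) -> "MarginalTable":
        keep = [i for i, t in enumerate(self.is_tip) if not t]
        return MarginalTable(
            tuple(self.node_ids[i] for i in keep),
            self.probs[keep],
            self.states,
            tuple(False for _ in keep),
            tuple(self.ages[i] for i in keep) if self.ages else (),
        )

    def row(self, node_id: str) -> np.ndarray:
        return self.probs[self.node_ids.index(node_id)]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.probs, columns=list(self.states))
        df.insert(0, "node", list(self.node_ids))
        df.insert(1, "is_tip", list(self.is_tip))
        if self.ages:
            df.insert(2, "age", list(self.ages))
        return df


def marginal_ancestral(
    tt: TimeTree,
    q: np.ndarray,
    tips: TipData,
    root_prior="flat",
    include_tips: bool = False,
    clamp_known_tips: bool = True,
) -> MarginalTable:
    """Two-pass marginal ancestral state estimates, collapsed to observed
    states.

    With ``include_tips`` every tip also receives a marginal; by default a
    tip with a (partially) known coding stays clamped to it, while
    ``clamp_known_tips=False`` re-estimates tips from the rest of the tree
    (the behaviour cross-validation needs for its held-out tip).
    """
    ctx, partials, _log_scale, ps = _postorder_partials(tt, q, tips)
    nodes, children = ctx.nodes, ctx.children
    n_model = tips.space.n_model
    root_idx = len(nodes) - 1
    pi = _root_prior_vector(root_prior, partials[root_idx], q)

    # preorder "outside" vectors: evidence from everywhere except the subtree
    outside = np.zeros_like(partials)
    outside[root_idx] = pi
    down = {}  # (parent_pos, child_pos) -> P @ partial[child]
    for i, ch in enumerate(children):
        for ci, ei in ch:
            down[(i, ci)] = ps[ei] @ partials[ci]
    for i in range(len(nodes) - 1, -1, -1):  # reverse postorder = preorder
        for ci, ei in children[i]:
            sib = np.ones(n_model)
            for ci2, _e2 in children[i]:
                if ci2 != ci:
                    sib *= down[(i, ci2)]
            msg = outside[i] * sib
            out = ps[ei].T @ msg
            top = out.max()
            outside[ci] = out / top if top > 0 else out

    rows, ids, is_tip, ages = [], [], [], []
    for i, node in enumerate(nodes):
        tip = node.is_leaf()
        if tip and not include_tips:
            continue
        if tip and not clamp_known_tips:
            # re-estimate the tip from the rest of the tree alone
            vec = outside[i]
        else:
            # internal nodes; tips keep their own (possibly ambiguous) evidence
            vec = partials[i] * outside[i]
        s = vec.sum()
        if s <= 0:
            raise LikelihoodError("zero marginal at a node")
        collapsed = tips.space.collapse(vec / s)
        rows.append(collapsed)
        ids.append(node.taxon.label if tip else node.label)
        is_tip.append(tip)
        ages.append(float(node.age) if hasattr(node, "age") else float("nan"))
    return MarginalTable(
        tuple(ids), np.vstack(rows), tips.space.observed_states,
        tuple(is_tip), tuple(ages),
    )


def aggregate_states(table: MarginalTable, grouping: Mapping[str, str]) -> MarginalTable:
    """Sum observed-state probabilities into groups (e.g. collapse the five
    feather morphotypes onto a single 'feathers' state)."""
    missing = [s for s in table.states if s not in grouping]
    if missing:
        raise LikelihoodError(f"grouping misses states: {missing}")
    groups = list(dict.fromkeys(grouping[s] for s in table.states))
    probs = np.zeros((table.probs.shape[0], len(groups)))
    for i, s in enumerate(table.states):
        probs[:, groups.index(grouping[s])] += table.probs[:, i]
    return MarginalTable(table.node_ids, probs, tuple(groups), table.is_tip, table.ages)
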