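"""Model-evaluation layer: information criteria, uncertainty, mutual
information, leave-one-out cross-validation, and model averaging.

Fit statistics (AIC, AICc and Akaike weights) measure how well a model
explains the observed tip states; *raw uncertainty* and *mutual information*
measure how decisive the resulting ancestral estimates are; LOOCV measures
generalizability -- how well a refitted model predicts the state of a
held-out tip. Model-averaged marginals combine the per-model ancestral
estimates with either Akaike weights or LOOCV error weights.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .likelihood import (
    FitOptions,
    FitResult,
    MarginalTable,
    TipData,
    fit_model,
    marginal_ancestral,
)
from .models import RateTemplate, build_q
from .trees import TimeTree, drop_tip

__all__ = [
    "ModelScore",
    "aic_scores",
    "akaike_weights",
    "raw_uncertainty",
    "proportion_of_max",
    "mutual_information",
    "loocv",
    "loocv_ingroup",
    "LoocvResult",
    "error_weights",
    "model_average",
    "select_generalizable",
]


class EvaluationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# information criteria
# ---------------------------------------------------------------------------


def aic_scores(fits: Sequence[FitResult]) -> dict:
    """AIC, AICc and delta-AIC for a compared set of fits.

    AICc = AIC + 2k(k+1)/(n-k-1); a fit with n - k - 1 <= 0 (the
    overparameterized case, e.g. a model with as many free parameters as
    tips) has its AICc flagged None and is excluded from AICc deltas.
    """
    if not fits:
        raise EvaluationError("no fits to score")
    aic = np.array([f.aic for f in fits])
    aicc = [f.aicc for f in fits]
    delta_aic = aic - aic.min()
    finite_aicc = [a for a in aicc if a is not None]
    min_aicc = min(finite_aicc) if finite_aicc else None
    delta_aicc = [None if a is None else a - min_aicc for a in aicc]
    return {
        "aic": aic.tolist(),
        "aicc": aicc,
        "delta_aic": delta_aic.tolist(),
        "delta_aicc": delta_aicc,
    }


def akaike_weights(deltas: Sequence[float]) -> np.ndarray:
    """w_i = exp(-Delta_i/2) / sum_k exp(-Delta_k/2)."""
    deltas = np.asarray(list(deltas), dtype=float)
    if deltas.size == 0:
        raise EvaluationError("empty delta list")
    if not np.isfinite(deltas).all():
        raise EvaluationError("non-finite AIC differences")
    w = np.exp(-0.5 * (deltas - deltas.min()))
    return w / w.sum()


# ---------------------------------------------------------------------------
# uncertainty and information
# ---------------------------------------------------------------------------


def raw_uncertainty(table: MarginalTable, internal_only: bool = True) -> float:
    """Raw uncertainty in percent: 100 * (1 - mean over nodes of the highest
    marginal state probability). 0 means every node is certain."""
    t = table.internal() if internal_only else table
    if t.probs.shape[0] == 0:
        raise EvaluationError("no nodes to score")
    return float(100.0 * (1.0 - t.probs.max(axis=1).mean()))


def proportion_of_max(uncertainty_percent: float, k: int) -> float:
    """Uncertainty as a fraction of its theoretical maximum 100*(1 - 1/k)."""
    if k < 2:
        raise EvaluationError("need at least two states")
    return float(uncertainty_percent / (100.0 * (1.0 - 1.0 / k)))


def _entropy_bits(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, -p * np.log2(np.where(p > 0, p, 1.0)), 0.0)
    return terms.sum(axis=-1)


def mutual_information(
    table: MarginalTable, k_observed: int | None = None, internal_only: bool = True
) -> dict:
    """Per-node and total mutual information in bits.

    The unconditional node-state entropy is fixed at log2(k) -- the model-set
    upper limit of what the tips can teach us about a node -- and the
    data-conditioned entropy is the entropy of the node's marginal, so
    MI(node) = log2(k) - H(marginal) in [0, log2 k].
    """
    t = table.internal() if internal_only else table
    if t.probs.shape[0] == 0:
        raise EvaluationError("no nodes to score")
    k = k_observed or len(t.states)
    per_node = np.log2(k) - _entropy_bits(t.probs)
    return {
        "per_node": dict(zip(t.node_ids, per_node.tolist())),
        "total": float(per_node.sum()),
    }


# ---------------------------------------------------------------------------
# leave-one-out cross-validation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LoocvResult:
    """Per-tip prediction errors from leave-one-out cross-validation."""

    errors: dict  # taxon -> 1 - p(true state set)
    predictive_logliks: dict  # taxon -> log p(true state set)
    failed: tuple[str, ...]

    @property
    def mean_error(self) -> float:
        vals = list(self.errors.values())
        return float(np.mean(vals)) if vals else float("nan")

    @property
    def mean_loglik(self) -> float:
        vals = list(self.predictive_logliks.values())
        return float(np.mean(vals)) if vals else float("nan")


def loocv(
    tt: TimeTree,
    template: RateTemplate,
    tips: TipData,
    options: FitOptions = FitOptions(),
    taxa: Sequence[str] | None = None,
    full_fit: FitResult | None = None,
) -> LoocvResult:
    """Leave-one-out cross-validation of one tree/model combination.

    For each scored tip: (1) drop the tip and refit the rates on the pruned
    tree; (2) restore the tip with its state set to unknown; (3) estimate the
    tip's marginal under the saved rates; (4) score
    ``error = 1 - sum of predicted probabilities over the true state set``
    (equivalently the summed probability of the incorrect states).

    Folds refit starting from the full-data MLE (plus the configured random
    restarts). A fold whose refit fails is flagged and excluded from the mean
    with a warning. ``taxa`` restricts the scored folds (ingroup-only LOOCV
    passes the ingroup here).
    """
    if len(tips.taxa) < 3:
        raise EvaluationError("LOOCV needs at least three tips")
    folds = list(taxa) if taxa is not None else list(tips.taxa)
    unknown = [t for t in folds if t not in tips.taxa]
    if unknown:
        raise EvaluationError(f"fold taxa not in data: {unknown}")
    if full_fit is None:
        full_fit = fit_model(tt, template, tips, options)
    fold_opts = FitOptions(
        n_starts=max(1, options.n_starts // 2),
        seed=options.seed,
        bounds=options.bounds,
        maxiter=options.maxiter,
        root_prior=options.root_prior,
        init=tuple(full_fit.rates),
    )
    errors, logliks, failed = {}, {}, []
    for taxon in folds:
        try:
            pruned = drop_tip(tt, taxon)
            fit = fit_model(pruned, template, tips.without(taxon), fold_opts)
            q = build_q(template, fit.rates)
            marg = marginal_ancestral(
                tt, q, tips.with_unknown(taxon),
                root_prior=options.root_prior,
                include_tips=True, clamp_known_tips=False,
            )
            pred = marg.row(taxon)
            p_true = float(pred[tips.true_observed_set(taxon)].sum())
        except Exception as exc:  # refit failure on a fold
            warnings.warn(f"LOOCV fold {taxon!r} failed: {exc}")
            failed.append(taxon)
            continue
        errors[taxon] = 1.0 - p_true
        logliks[taxon] = math.log(max(p_true, 1e-300))
    return LoocvResult(errors, logliks, tuple(failed))


def loocv_ingroup(
    tt: TimeTree,
    template: RateTemplate,
    tips: TipData,
    ingroup: Sequence[str],
    options: FitOptions = FitOptions(),
    full_fit: FitResult | None = None,
) -> LoocvResult:
    """LOOCV dropping and scoring only ingroup taxa.

    The outgroup stays in every fold, so trees that differ only in outgroup
    composition score the identical set of taxa and their mean errors are
    directly comparable.
    """
    ingroup = list(ingroup)
    if not ingroup:
        raise EvaluationError("empty ingroup")
    if not set(ingroup) <= set(tips.taxa):
        raise EvaluationError("ingroup taxa missing from data")
    return loocv(tt, template, tips, options, taxa=ingroup, full_fit=full_fit)


# ---------------------------------------------------------------------------
# weighting, averaging, selection
# ---------------------------------------------------------------------------


def error_weights(mean_errors: Sequence[float]) -> np.ndarray:
    """w_i = (1 - e_i) / sum_j (1 - e_j) for LOOCV mean errors in [0, 1]."""
    e = np.asarray(list(mean_errors), dtype=float)
    if e.size == 0:
        raise EvaluationError("empty error list")
    if ((e < 0) | (e > 1)).any():
        raise EvaluationError("errors must lie in [0, 1]")
    s = (1.0 - e).sum()
    if s <= 0:
        warnings.warn("all models have error 1; falling back to uniform weights")
        return np.full(e.size, 1.0 / e.size)
    return (1.0 - e) / s


def model_average(
    tables: Sequence[MarginalTable], weights: Sequence[float]
) -> MarginalTable:
    """Weighted sum of marginal tables over a common tree topology."""
    if len(tables) != len(weights):
        raise EvaluationError("one weight per table required")
    w = np.asarray(list(weights), dtype=float)
    if not math.isclose(float(w.sum()), 1.0, abs_tol=1e-6):
        raise EvaluationError("weights must sum to 1")
    first = tables[0]
    for t in tables[1:]:
        if t.node_ids != first.node_ids or t.states != first.states:
            raise EvaluationError("marginal tables disagree on nodes or states")
    probs = sum(wi * t.probs for wi, t in zip(w, tables))
    return MarginalTable(first.node_ids, probs, first.states, first.is_tip, first.ages)


def select_generalizable(
    mean_errors: Mapping[str, float], threshold: float = 0.10
) -> list[str]:
    """Combinations whose LOOCV mean error lies within ``threshold`` (a
    fraction) of the lowest mean error: e_i <= (1 + threshold) * min e."""
    finite = {k: v for k, v in mean_errors.items() if np.isfinite(v)}
    if not finite:
        raise EvaluationError("no finite mean errors")
    cutoff = (1.0 + threshold) * min(finite.values())
    return [k for k, v in finite.items() if v <= cutoff + 1e-12]


@dataclass(frozen=True)
class ModelScore:
    """Evaluation record for one tree/model combination."""

    model_id: str
    tree_id: str
    fit: FitResult
    uncertainty_percent: float
    proportion_of_max: float
    mutual_information_total: float
    mutual_information_per_node: dict
    loocv: LoocvResult | None = None

    @property
    def aic(self) -> float:
        return self.fit.aic

    @property
    def aicc(self) -> float | None:
        return self.fit.aicc

    @property
    def loocv_mean_error(self) -> float:
        return self.loocv.mean_error if self.loocv is not None else float("nan")
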