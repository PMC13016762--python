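"""Experiment orchestration: grids of tree/coding/model combinations.

The four study axes are outgroup composition, a-posteriori time-scaling
method, character coding strategy, and evolutionary model. ``run_experiment``
executes every requested cell (fit + marginal ancestral estimates + scores),
then derives cross-cell products: delta-AIC/Akaike weights, the LOOCV ranking
with its generalizability threshold, and model-averaged marginals under both
Akaike weights and LOOCV error weights. ``tabulate`` lays the bundle out as
the familiar comparison tables.

The full study grid (7 architectures x 3 schemes x 3 time-scalings = 63
combinations) with full LOOCV is thousands of model fits; ``loocv_scope``
and ``loocv_max_folds`` restrict the folds or cells for exploratory runs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import evaluation as ev
from .likelihood import FitOptions, encode_tips, fit_model, marginal_ancestral
from .models import (
    ARCHITECTURES,
    SCHEMES,
    build_q,
    feather_hierarchy,
    model_grid,
)
from .simulate import SimConfig, coding_labels, make_feather_like_dataset, recode
from .trees import TaxonAges, TimeTree, read_ages, read_tree, timescale_equal, timescale_mbl
from .io import read_character_matrix

__all__ = ["ExperimentConfig", "run_experiment", "tabulate", "TIMESCALINGS"]

TIMESCALINGS = ("equal_basal", "equal_legacy", "mbl")


class PipelineError(RuntimeError):
    pass


@dataclass
class ExperimentConfig:
    """One experiment request.

    Either ``tree/ages/matrix`` paths or a synthetic ``sim`` block supplies
    the data. ``outgroups`` maps a name to the outgroup taxa used for that
    variant (all other outgroup candidates are pruned); by default a single
    variant keeps everything.
    """

    tree: str | None = None
    ages: str | None = None
    matrix: str | None = None
    sim: SimConfig | None = SimConfig()
    outgroups: dict | None = None  # name -> list of taxa
    timescalings: tuple[str, ...] = ("equal_basal",)
    codings: tuple[int, ...] = (3,)
    architectures: tuple[str, ...] = ARCHITECTURES
    schemes: tuple[str, ...] = SCHEMES
    ed_variant: str = "QL"
    root_length: float = 1.0
    min_length: float = 1.0
    root_prior: str = "flat"
    n_starts: int = 3
    maxiter: int = 200
    seed: int = 1
    loocv_scope: str = "none"  # none | full | ingroup
    loocv_max_folds: int | None = None
    loocv_architectures: tuple[str, ...] | None = None
    generalizability_threshold: float = 0.10
    focal_node: str | None = None
    outdir: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "sim" in raw and raw["sim"] is not None:
            raw["sim"] = SimConfig(**raw["sim"])
        for key in ("timescalings", "codings", "architectures", "schemes"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def config_hash(self) -> str:
        payload = {k: (asdict(v) if isinstance(v, SimConfig) else v)
                   for k, v in asdict(self).items()}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


def _load_inputs(config: ExperimentConfig):
    if config.tree is not None:
        topology = read_tree(config.tree, "nexus" if str(config.tree).endswith((".nex", ".nexus")) else "newick")
        ages = read_ages(config.ages)
        codes = read_character_matrix(config.matrix)
        outgroups = config.outgroups or {"all": []}
        return topology, ages, codes, outgroups
    if config.sim is None:
        raise PipelineError("config must supply either file paths or a sim block")
    data = make_feather_like_dataset(config.sim)
    topology = data["tree"].tree
    outgroups = config.outgroups or {"default": data["outgroup"]}
    return topology, data["ages"], data["codes"], outgroups


def _scaled_tree(method: str, topology, ages: TaxonAges, config: ExperimentConfig) -> TimeTree:
    if method == "equal_basal":
        return timescale_equal(topology, ages, config.root_length, ordering="basal_first")
    if method == "equal_legacy":
        return timescale_equal(topology, ages, config.root_length, ordering="legacy")
    if method == "mbl":
        return timescale_mbl(topology, ages, config.min_length, config.root_length)
    raise PipelineError(f"unknown time-scaling method {method!r}")


def _restrict(topology, codes, keep: set[str]):
    tree = topology.clone(depth=1)
    drop = {l for l in (leaf.taxon.label for leaf in tree.leaf_node_iter())
            if l not in keep}
    if drop:
        tree.prune_taxa([t for t in tree.taxon_namespace if t.label in drop])
    sub_codes = {t: codes[t] for t in codes if t in keep}
    return tree, sub_codes


def run_experiment(config: ExperimentConfig) -> dict:
    """Run every requested grid cell and the cross-cell summaries.

    Returns a bundle dict: ``cells`` (list of per-cell records), ``summary``
    (a tidy DataFrame), ``averaged`` (model-averaged marginal tables per
    tree/coding, when computable), and ``provenance``. Cell failures are
    recorded under ``failures`` rather than aborting the bundle.
    """
    topology, ages, codes6, outgroups = _load_inputs(config)
    all_taxa = {leaf.taxon.label for leaf in topology.leaf_node_iter()}
    outgroup_union: set[str] = set().union(*outgroups.values()) if outgroups else set()
    ingroup = all_taxa - outgroup_union

    cells, failures = [], []
    marginals: dict[tuple, object] = {}
    for og_name, og_taxa in outgroups.items():
        keep = ingroup | set(og_taxa)
        sub_topology, sub_codes6 = _restrict(topology, codes6, keep)
        for method in config.timescalings:
            tt = _scaled_tree(method, sub_topology, ages, config)
            for coding in config.codings:
                codes = recode(sub_codes6, coding)
                labels = coding_labels(coding)
                n_states = len(labels)
                hierarchy = feather_hierarchy(coding) if coding in (2, 3) else None
                archs = config.architectures if n_states > 2 else ("unordered",)
                grid = model_grid(
                    n_states=n_states,
                    hierarchy=hierarchy,
                    ed_variant=config.ed_variant,
                    architectures=archs,
                    schemes=config.schemes,
                )
                for model_id, template in grid.items():
                    tree_id = f"{og_name}/{method}/coding{coding}"
                    opts = FitOptions(
                        n_starts=config.n_starts, seed=config.seed,
                        maxiter=config.maxiter, root_prior=config.root_prior,
                    )
                    try:
                        cell = _run_cell(
                            tt, template, codes, labels, opts, config,
                            model_id, tree_id, ingroup,
                        )
                    except Exception as exc:
                        failures.append({"tree": tree_id, "model": model_id,
                                         "error": str(exc)})
                        continue
                    cells.append(cell)
                    marginals[(tree_id, model_id)] = cell["marginal"]

    summary = _summarize(cells, config)
    averaged = _model_averages(cells, marginals, config)
    bundle = {
        "cells": cells,
        "failures": failures,
        "summary": summary,
        "averaged": averaged,
        "provenance": {
            "seed": config.seed,
            "config_hash": config.config_hash(),
            "n_cells": len(cells),
        },
    }
    if config.outdir:
        _write_bundle(bundle, config)
    return bundle


def _run_cell(tt, template, codes, labels, opts, config, model_id, tree_id, ingroup):
    tips = encode_tips(codes, template.space, tree_taxa=tt.tip_labels())
    fit = fit_model(tt, template, tips, opts)
    q = build_q(template, fit.rates)
    marg = marginal_ancestral(tt, q, tips, root_prior=config.root_prior)
    unc = ev.raw_uncertainty(marg)
    mi = ev.mutual_information(marg, k_observed=len(labels))
    loo = None
    arch = model_id.rsplit(" ", 1)[0]
    wants_loocv = config.loocv_scope != "none" and (
        config.loocv_architectures is None or arch in config.loocv_architectures
    )
    if wants_loocv:
        folds = sorted(ingroup & set(tips.taxa)) if config.loocv_scope == "ingroup" \
            else list(tips.taxa)
        if config.loocv_max_folds is not None:
            folds = folds[: config.loocv_max_folds]
        loo = ev.loocv(tt, template, tips, opts, taxa=folds, full_fit=fit)
    score = ev.ModelScore(
        model_id=model_id,
        tree_id=tree_id,
        fit=fit,
        uncertainty_percent=unc,
        proportion_of_max=ev.proportion_of_max(unc, len(labels)),
        mutual_information_total=mi["total"],
        mutual_information_per_node=mi["per_node"],
        loocv=loo,
    )
    return {
        "tree": tree_id,
        "model": model_id,
        "score": score,
        "marginal": marg,
        "tips": tips,
        "time_tree": tt,
    }


def _summarize(cells, config) -> pd.DataFrame:
    rows = []
    for cell in cells:
        s: ev.ModelScore = cell["score"]
        row = {
            "tree": s.tree_id,
            "model": s.model_id,
            "n_params": s.fit.n_params,
            "lnL": s.fit.loglik,
            "AIC": s.aic,
            "AICc": s.aicc,
            "uncertainty_pct": s.uncertainty_percent,
            "prop_max_uncertainty": s.proportion_of_max,
            "MI_total_bits": s.mutual_information_total,
            "loocv_mean_error": s.loocv_mean_error,
        }
        if config.focal_node is not None:
            row["MI_focal_bits"] = s.mutual_information_per_node.get(config.focal_node)
        rows.append(row)
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    df["AICc"] = pd.to_numeric(df["AICc"], errors="coerce")
    df["delta_AIC"] = df["AIC"] - df["AIC"].min()
    df["akaike_weight"] = ev.akaike_weights(df["delta_AIC"])
    finite_aicc = df["AICc"].dropna()
    df["delta_AICc"] = df["AICc"] - (finite_aicc.min() if not finite_aicc.empty else np.nan)
    if df["loocv_mean_error"].notna().any():
        errs = {f"{r.tree}|{r.model}": r.loocv_mean_error
                for r in df.itertuples() if np.isfinite(r.loocv_mean_error)}
        chosen = set(ev.select_generalizable(errs, config.generalizability_threshold))
        df["generalizable"] = [
            f"{r.tree}|{r.model}" in chosen for r in df.itertuples()
        ]
    return df


def _model_averages(cells, marginals, config):
    """AIC-weight and LOOCV-error-weight model averages per comparable block.

    Averaging needs identical node sets, so it runs within each tree/coding
    block (cells sharing a tree id).
    """
    out = {}
    by_tree: dict[str, list] = {}
    for cell in cells:
        by_tree.setdefault(cell["tree"], []).append(cell)
    for tree_id, group in by_tree.items():
        tables = [c["marginal"] for c in group]
        aics = np.array([c["score"].aic for c in group])
        w_aic = ev.akaike_weights(aics - aics.min())
        entry = {"aic_weights": dict(zip((c["model"] for c in group), w_aic.tolist())),
                 "aic_averaged": ev.model_average(tables, w_aic)}
        errs = [c["score"].loocv_mean_error for c in group]
        if all(np.isfinite(e) for e in errs):
            w_err = ev.error_weights(errs)
            entry["error_weights"] = dict(zip((c["model"] for c in group), w_err.tolist()))
            entry["error_averaged"] = ev.model_average(tables, w_err)
        out[tree_id] = entry
    return out


# ---------------------------------------------------------------------------
# tables
# ---------------------------------------------------------------------------

_LAYOUTS = {
    "table3": ("outgroup", "uncertainty_pct"),
    "table4": ("outgroup", "loocv_mean_error"),
    "table5": ("outgroup", "MI_focal_bits"),
    "table6": ("timescaling", None),  # uncertainty + AICc side by side
    "table7": ("coding", "uncertainty_pct"),
}


def tabulate(bundle: dict, layout: str) -> pd.DataFrame:
    """Lay a bundle out as one of the comparison tables.

    table3: uncertainty by outgroup; table4: ingroup LOOCV mean error by
    outgroup; table5: focal-node mutual information by outgroup; table6:
    uncertainty and AICc by time-scaling; table7: uncertainty by coding
    strategy. Columns are the transition-rate schemes.
    """
    if layout not in _LAYOUTS:
        raise PipelineError(f"unknown layout {layout!r}")
    df = bundle["summary"]
    if df is None or df.empty:
        raise PipelineError("empty bundle")
    df = df.copy()
    parts = df["tree"].str.split("/", expand=True)
    df["outgroup"], df["timescaling"], df["coding"] = parts[0], parts[1], parts[2]
    df["scheme"] = df["model"].str.rsplit(" ", n=1).str[1]
    row_key, value = _LAYOUTS[layout]
    # each layout varies one axis; pin the others to their first level present
    for axis in ("outgroup", "timescaling", "coding"):
        if axis != row_key:
            df = df[df[axis] == df[axis].iloc[0]]
    if layout == "table6":
        sub = df.pivot_table(
            index="timescaling", columns="scheme",
            values=["uncertainty_pct", "AICc"], aggfunc="first", sort=False,
        )
        return sub.round(4)
    if value not in df.columns or df[value].isna().all():
        raise PipelineError(f"bundle lacks the metric for {layout}")
    return df.pivot_table(
        index=row_key, columns="scheme", values=value, aggfunc="first", sort=False
    ).round(4)


def _write_bundle(bundle: dict, config: ExperimentConfig) -> None:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    df = bundle["summary"]
    df.to_csv(outdir / "summary.tsv", sep="\t", index=False, float_format="%.6f")
    for (tree_id), entry in bundle["averaged"].items():
        safe = tree_id.replace("/", "_")
        entry["aic_averaged"].to_frame().to_csv(
            outdir / f"averaged_aic_{safe}.tsv", sep="\t", index=False,
            float_format="%.6f",
        )
        if "error_averaged" in entry:
            entry["error_averaged"].to_frame().to_csv(
                outdir / f"averaged_error_{safe}.tsv", sep="\t", index=False,
                float_format="%.6f",
            )
    (outdir / "provenance.json").write_text(
        json.dumps(bundle["provenance"], indent=1, sort_keys=True)
    )
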