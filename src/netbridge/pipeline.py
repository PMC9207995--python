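"""End-to-end orchestration: QC -> residualization -> per-trait CPM ->
total brain scores -> joint behaviour+brain networks (GGM + PDAG).

A single master seed deterministically derives one seed per stage (SHA-256
of ``"<master>:<stage>"``), so any stage can be re-run in isolation and a
repeated run produces a byte-identical report.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .bayesnet import consensus_structure, learn_structure
from .behaviour import (BehaviourTable, correlation_table, residualize_full,
                        residualize_sequential)
from .connectome import EdgeTable, regress_confounds
from .cpm import (consensus_edges, fit_cpm_sets, per_split_selections,
                  permutation_test, total_brain_score, tune_cpm)
from .ggm import GGMError, bootstrap_network, estimate_network, network_edge_list

__all__ = [
    "RunConfig",
    "RunReport",
    "PipelineError",
    "stage_seed",
    "qc_filter_subjects",
    "assemble_joint_table",
    "run_pipeline",
]

log = logging.getLogger(__name__)

DEFAULTS: dict = {
    "seed": 0,
    "output_dir": "netbridge_out",
    "inputs": {"behaviour_csv": None, "confounds_csv": None, "channels": []},
    "qc": {"fd_max": 0.5, "dvars_max": 5.0},
    "confound_regression": True,
    "residualization": {"scheme": "sequential", "order": None},
    "cpm": {"p_grid": [0.01, 0.05], "n_outer": 10, "outer_test_fraction": 0.2,
            "inner_folds": 10, "min_count": 7, "n_perm": 0},
    "ggm": {"gamma": 0.5, "bootstrap_B": 0},
    "bayesnet": {"algorithms": ["gs", "iamb"], "tests": ["fisher_z"],
                 "alpha": 0.05, "mc_B": 199},
    "simulate": None,
}


class PipelineError(RuntimeError):
    def __init__(self, stage: str, code: str, message: str):
        super().__init__(f"[{stage}:{code}] {message}")
        self.stage = stage
        self.code = code


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


@dataclass
class RunConfig:
    """Validated run configuration (YAML-backed, see DEFAULTS for fields)."""

    raw: dict
    base_dir: Path = field(default_factory=Path)

    def __post_init__(self) -> None:
        self.raw = _merge(DEFAULTS, self.raw)
        if self.raw.get("seed") is None:
            raise ValueError("config must set an integer master seed")
        for key, sub in (("qc", "fd_max"), ("qc", "dvars_max"),
                         ("cpm", "outer_test_fraction")):
            if self.raw[key][sub] <= 0:
                raise ValueError(f"{key}.{sub} must be positive")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        path = Path(path)
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(raw, base_dir=path.parent)

    def __getitem__(self, key):
        return self.raw[key]

    def path(self, rel) -> Path:
        p = Path(rel)
        return p if p.is_absolute() else self.base_dir / p

    def validate_inputs(self) -> None:
        inp = self.raw["inputs"]
        for key in ("behaviour_csv", "confounds_csv"):
            if inp.get(key) is None or not self.path(inp[key]).exists():
                raise PipelineError("load", "missing_input",
                                    f"inputs.{key} missing or not found: {inp.get(key)}")
        if not inp["channels"]:
            raise PipelineError("load", "missing_input", "no channels configured")
        for ch in inp["channels"]:
            if not self.path(ch["edges_csv"]).exists():
                raise PipelineError("load", "missing_input",
                                    f"channel file not found: {ch['edges_csv']}")


@dataclass
class RunReport:
    """JSON-serializable master report; every number is recomputable from
    config + inputs + master seed."""

    content: dict

    def to_json(self, path=None) -> str:
        text = json.dumps(self.content, sort_keys=True, indent=2,
                          default=_jsonify)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


def _jsonify(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed: first 4 bytes of SHA-256('<master>:<stage>')."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "little")


def qc_filter_subjects(metrics: pd.DataFrame, fd_max: float = 0.5,
                       dvars_max: float = 5.0
                       ) -> tuple[list, list[tuple[str, str]]]:
    """Exclude subjects with FD > fd_max (mm) or DVARS > dvars_max (%).

    Boundary values are kept (strictly-greater exclusion).  Missing
    metrics exclude the subject with reason ``missing_qc``.
    """
    kept, excluded = [], []
    for sid, row in metrics.iterrows():
        fd, dvars = row.get("fd"), row.get("dvars")
        if fd is None or dvars is None or pd.isna(fd) or pd.isna(dvars):
            excluded.append((sid, "missing_qc"))
        elif fd > fd_max:
            excluded.append((sid, "fd"))
        elif dvars > dvars_max:
            excluded.append((sid, "dvars"))
        else:
            kept.append(sid)
    return kept, excluded


def assemble_joint_table(behaviour: BehaviourTable,
                         total_scores: dict[str, pd.Series]) -> pd.DataFrame:
    """Columns [trait scores..., trait brain scores...] in trait order,
    complete-case rows only."""
    traits = behaviour.traits
    if sorted(total_scores.keys()) != sorted(traits):
        raise ValueError(f"need one total score per trait {traits}, "
                         f"got {sorted(total_scores)}")
    df = behaviour.data[traits].copy()
    for t in traits:
        s = total_scores[t]
        if not s.index.equals(df.index):
            raise ValueError(f"total score for {t!r} has misaligned subject ids")
        df[f"{t}_brain"] = s
    return df.dropna()


def _load_channels(config: RunConfig) -> dict[tuple, EdgeTable]:
    channels = {}
    for ch in config["inputs"]["channels"]:
        key = (int(ch["resolution"]), str(ch["metric"]), bool(ch.get("gsr", False)))
        channels[key] = EdgeTable.from_csv(config.path(ch["edges_csv"]),
                                           metric=key[1], gsr=key[2])
    return channels


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute the full analysis and write report + artefacts.

    Stage failures abort with a :class:`PipelineError` carrying the stage
    name and a machine-readable code.
    """
    master = int(config["seed"])
    outdir = config.path(config["output_dir"])
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"software_version": __version__, "master_seed": master,
                    "config": config.raw, "stages": []}

    def stage_done(name: str, **info):
        report["stages"].append({"stage": name, "status": "ok", **info})
        log.info("stage=%s status=ok %s", name, info)

    # ---- load -------------------------------------------------------
    config.validate_inputs()
    behaviour = BehaviourTable.from_csv(config.path(config["inputs"]["behaviour_csv"]))
    confounds = pd.read_csv(config.path(config["inputs"]["confounds_csv"]),
                            index_col="subject_id")
    channels = _load_channels(config)
    stage_done("load", n_subjects=behaviour.n_subjects,
               n_channels=len(channels))

    # ---- quality control -------------------------------------------
    qc = config["qc"]
    kept, excluded = qc_filter_subjects(confounds, qc["fd_max"], qc["dvars_max"])
    behaviour = BehaviourTable(behaviour.data.loc[kept])
    confounds = confounds.loc[kept]
    channels = {k: EdgeTable(v.data.loc[kept], v.pairs, metric=v.metric,
                             gsr=v.gsr) for k, v in channels.items()}
    report["qc"] = {"kept": len(kept),
                    "excluded": [{"subject": str(s), "reason": r}
                                 for s, r in excluded]}
    stage_done("qc", kept=len(kept), excluded=len(excluded))

    # ---- confound regression ---------------------------------------
    if config["confound_regression"]:
        conf_cols = [c for c in ("age", "site", "fd", "dvars", "icv",
                                 "gm_volume") if c in confounds.columns]
        channels = {k: regress_confounds(v, confounds[conf_cols])
                    for k, v in channels.items()}
        stage_done("confound_regression", confounds=conf_cols)
    else:
        report["stages"].append({"stage": "confound_regression",
                                 "status": "not run"})

    # ---- residualization -------------------------------------------
    res_cfg = config["residualization"]
    traits = behaviour.traits
    try:
        if res_cfg["scheme"] == "sequential":
            order = res_cfg.get("order") or traits
            behaviour, models = residualize_sequential(behaviour, order)
        elif res_cfg["scheme"] == "full":
            behaviour, models = residualize_full(behaviour)
        else:
            raise ValueError(f"unknown scheme {res_cfg['scheme']!r}")
    except ValueError as exc:
        raise PipelineError("residualize", "invalid", str(exc)) from exc
    all_cols = traits + [f"{t}_residual" for t in traits]
    report["behaviour_correlations"] = (
        correlation_table(behaviour, columns=all_cols).round(10)
        .to_dict())
    report["residualization"] = {
        "scheme": res_cfg["scheme"],
        "order": models[0].order if models[0].order else None,
        "complete_case_n": models[0].n_used,
    }
    stage_done("residualize", scheme=res_cfg["scheme"], n_traits=len(traits))

    # ---- per-trait CPM ---------------------------------------------
    cpm_cfg = config["cpm"]
    total_scores: dict[str, pd.Series] = {}
    report["cpm"] = {}
    for trait in traits:
        y = behaviour.data[f"{trait}_residual"]
        seed = stage_seed(master, f"cpm:{trait}")
        tuning = tune_cpm(channels, y, cpm_cfg["p_grid"],
                          n_outer=cpm_cfg["n_outer"],
                          outer_test_fraction=cpm_cfg["outer_test_fraction"],
                          inner_folds=cpm_cfg["inner_folds"], seed=seed)
        best = tuning.best
        best_key = (best["resolution"], best["metric"], best["gsr"])
        best_edges = channels[best_key]
        selections = per_split_selections(best_edges, y, best["p_threshold"],
                                          tuning.splits)
        consensus = consensus_edges(selections, min_count=cpm_cfg["min_count"])
        tuning.table.to_csv(outdir / f"tuning_{trait}.csv", index=False)
        pd.DataFrame(
            [{"edge": e, "roi_a": best_edges.pairs[list(best_edges.data.columns).index(e)][0],
              "roi_b": best_edges.pairs[list(best_edges.data.columns).index(e)][1],
              "sign": sign}
             for sign, group in (("positive", consensus.positive),
                                 ("negative", consensus.negative))
             for e in group]
        ).to_csv(outdir / f"consensus_{trait}.csv", index=False)

        entry = {"best": best,
                 "consensus_positive": consensus.positive,
                 "consensus_negative": consensus.negative,
                 "sign_conflicts": consensus.sign_conflicts}
        if cpm_cfg["n_perm"] > 0:
            perm = permutation_test(
                best_edges, y, best["p_threshold"],
                n_outer=cpm_cfg["n_outer"],
                outer_test_fraction=cpm_cfg["outer_test_fraction"],
                n_perm=cpm_cfg["n_perm"], seed=seed)
            entry["permutation_p"] = perm.p_value
            entry["observed_mean_r"] = perm.observed
        else:
            entry["permutation"] = "not run"
        # full-sample refit on the consensus sets -> total brain score node
        model = fit_cpm_sets(best_edges, y, consensus.positive,
                             consensus.negative, best["p_threshold"])
        entry["coefficients"] = {"beta_pos": model.beta_pos,
                                 "beta_neg": model.beta_neg,
                                 "intercept": model.intercept,
                                 "degenerate": model.degenerate}
        total = total_brain_score(model, best_edges)
        total_scores[trait] = pd.Series(total, index=best_edges.data.index)
        report["cpm"][trait] = entry
        stage_done(f"cpm:{trait}", best=str(best_key),
                   p_threshold=best["p_threshold"])

    # ---- joint table ------------------------------------------------
    base_behaviour = BehaviourTable(behaviour.data[traits])
    joint = assemble_joint_table(base_behaviour, total_scores)
    joint.to_csv(outdir / "joint_table.csv", index_label="subject_id")
    report["joint_table"] = {
        "columns": list(joint.columns), "n_complete": len(joint),
        "n_dropped": behaviour.n_subjects - len(joint),
        "correlations": correlation_table(joint).round(10).to_dict(),
    }
    stage_done("joint_table", n_complete=len(joint))

    # ---- GGM --------------------------------------------------------
    # constant columns (degenerate intercept-only CPM models yield constant
    # brain scores) carry no correlation structure; drop them from the
    # network stages and record the exclusion
    constant_cols = [c for c in joint.columns if joint[c].nunique() <= 1]
    usable = [c for c in joint.columns if c not in constant_cols]
    report["joint_table"]["constant_columns"] = constant_cols

    ggm_cfg = config["ggm"]
    report["ggm"] = {}
    subnets = {"behaviour": [t for t in traits if t in usable],
               "brain": [f"{t}_brain" for t in traits
                         if f"{t}_brain" in usable],
               "combined": usable}
    for name, cols in subnets.items():
        if len(cols) < 2:
            report["ggm"][name] = "skipped: fewer than 2 usable nodes"
            report["stages"].append({"stage": f"ggm:{name}",
                                     "status": "skipped"})
            continue
        sub = joint[cols]
        seed = stage_seed(master, f"ggm:{name}")
        try:
            if ggm_cfg["bootstrap_B"] >= 100:
                boot = bootstrap_network(sub, B=ggm_cfg["bootstrap_B"],
                                         gamma=ggm_cfg["gamma"], seed=seed)
                edge_df = network_edge_list(boot)
                fit = boot.point_fit
            else:
                fit = estimate_network(sub, gamma=ggm_cfg["gamma"])
                edge_df = pd.DataFrame(
                    [{"node_a": a, "node_b": b, "weight": w}
                     for (a, b), w in fit.edge_weights().items()])
        except GGMError as exc:
            raise PipelineError(f"ggm:{name}", "fit_failed", str(exc)) from exc
        edge_df.to_csv(outdir / f"ggm_{name}.csv", index=False)
        report["ggm"][name] = {
            "nodes": fit.nodes, "n_edges": fit.n_edges,
            "edges": {f"{a}|{b}": round(w, 10)
                      for (a, b), w in fit.edge_weights().items()},
            "bootstrap": ("not run" if ggm_cfg["bootstrap_B"] < 100
                          else {"B": ggm_cfg["bootstrap_B"]}),
        }
        stage_done(f"ggm:{name}", n_edges=fit.n_edges)

    # ---- Bayesian networks -----------------------------------------
    bn_cfg = config["bayesnet"]
    bn_input = joint[usable]
    pdags, labels = [], []
    for alg in bn_cfg["algorithms"]:
        for test in bn_cfg["tests"]:
            seed = stage_seed(master, f"bayesnet:{alg}:{test}")
            pdag = learn_structure(bn_input, algorithm=alg, test=test,
                                   alpha=bn_cfg["alpha"], B=bn_cfg["mc_B"],
                                   seed=seed)
            pdags.append(pdag)
            labels.append(f"{alg}/{test}")
    cons, disagreements = consensus_structure(pdags)
    cons.edges_dataframe().to_csv(outdir / "pdag_consensus.csv", index=False)
    report["bayesnet"] = {
        "inputs": {lbl: p.to_dict() for lbl, p in zip(labels, pdags)},
        "consensus": cons.to_dict(),
        "disagreements": disagreements,
    }
    stage_done("bayesnet", n_learners=len(pdags),
               n_disagreements=len(disagreements))

    run_report = RunReport(report)
    run_report.to_json(outdir / "report.json")
    return run_report
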