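"""End-to-end orchestration: synth -> fit -> score -> split -> associate -> de -> enrich -> hubs.

A single YAML (or dict) config drives the run; all randomness flows from one
root seed; outputs land under ``<outdir>/<stage>/`` and a JSON manifest
records stage statuses, output paths and a hash of the effective parameters.
A stage failure halts everything downstream and is recorded in the manifest.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
from dataclasses import fields
from pathlib import Path

import pandas as pd
import yaml

from . import association, diffexpr, enrichment, io, network, stemness, synth
from .exceptions import ConfigError, StemdexError

log = logging.getLogger(__name__)

STAGES = ["synth", "fit", "score", "split", "associate", "de", "enrich", "hubs"]

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "outdir": "stemdex_run",
    "stages": {name: True for name in STAGES},
    "synth": {"n_gene_sets": 20},          # extra keys: any SynthConfig field
    "inputs": {},                           # train/expr/counts/clinical/gmt/edges when synth is off
    "stemness": {"penalty_l2": 1.0, "tol": 1e-6, "max_iter": 1000, "rescale": "minmax"},
    "associate": {"covariates": ["stage", "subtype"],
                  "endpoints": {"pfs": ["pfs_time", "pfs_event"],
                                "dss": ["dss_time", "dss_event"]}},
    "de": {"method": "nb", "min_total_count": 10},
    "enrich": {},
    "hubs": {"cutoff": 0.4, "top": 10, "method": "mcc"},
}


def _deep_merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _deep_merge(out[k], v)
        else:
            out[k] = copy.deepcopy(v)
    return out


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> dict:
    """Merge defaults <- YAML file <- explicit overrides."""
    cfg = copy.deepcopy(DEFAULT_CONFIG)
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, dict):
            raise ConfigError(f"config {path} must be a YAML mapping")
        cfg = _deep_merge(cfg, user)
    if overrides:
        cfg = _deep_merge(cfg, overrides)
    unknown = set(cfg) - set(DEFAULT_CONFIG)
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    unknown_stages = set(cfg["stages"]) - set(STAGES)
    if unknown_stages:
        raise ConfigError(f"unknown stage names: {sorted(unknown_stages)}")
    return cfg


def _synth_config(cfg: dict) -> synth.SynthConfig:
    params = {k: v for k, v in cfg["synth"].items() if k != "n_gene_sets"}
    valid = {f.name for f in fields(synth.SynthConfig)}
    unknown = set(params) - valid
    if unknown:
        raise ConfigError(f"unknown synth keys: {sorted(unknown)}")
    for key in ("purity_range", "clique_sizes"):
        if key in params:
            params[key] = tuple(params[key])
    return synth.SynthConfig(**params, seed=cfg["seed"]).validate()


def _validate_inputs(cfg: dict) -> None:
    """Every enabled stage must have its inputs available before anything runs."""
    on = cfg["stages"]
    if on.get("synth"):
        _synth_config(cfg)  # raises on bad parameters
        return
    needed = {"fit": ["train"], "score": ["expr", "clinical"],
              "associate": ["clinical"], "de": ["counts" if cfg["de"]["method"] == "nb" else "expr"],
              "enrich": ["gmt"], "hubs": ["edges"]}
    missing = []
    for stage, keys in needed.items():
        if not on.get(stage):
            continue
        for key in keys:
            path = cfg["inputs"].get(key)
            if path is None or not Path(path).exists():
                missing.append(f"{stage} needs inputs.{key}" + ("" if path is None else f" ({path} not found)"))
    if missing:
        raise ConfigError("missing inputs: " + "; ".join(missing))


def run(config: dict | str | Path, outdir: str | Path | None = None) -> dict:
    """Execute the enabled stages in dependency order; return the manifest."""
    cfg = load_config(config) if isinstance(config, (str, Path)) else load_config(overrides=config)
    if outdir is not None:
        cfg["outdir"] = str(outdir)
    _validate_inputs(cfg)
    out = Path(cfg["outdir"])
    out.mkdir(parents=True, exist_ok=True)

    param_hash = hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()
    manifest: dict = {"seed": cfg["seed"], "param_hash": param_hash, "stages": {}}
    state: dict = {}
    halted = False
    for stage in STAGES:
        entry = {"status": "skipped", "outputs": []}
        manifest["stages"][stage] = entry
        if halted or not cfg["stages"].get(stage, False):
            continue
        try:
            outputs = _STAGE_FUNCS[stage](cfg, state, out / stage)
            entry["status"] = "completed"
            entry["outputs"] = [str(p) for p in outputs]
        except StemdexError as exc:
            entry["status"] = "failed"
            entry["error"] = str(exc)
            log.error("stage %s failed: %s", stage, exc)
            halted = True
    io.write_json(manifest, out / "manifest.json")
    return manifest


# --- stage implementations ------------------------------------------------

def _stage_synth(cfg, state, d: Path):
    scfg = _synth_config(cfg)
    train = synth.generate_training_set(scfg)
    reference = synth.generate_progenitor_set(scfg)
    expr, counts, clinical, truth = synth.generate_tumor_cohort(scfg)
    edges = synth.generate_network(truth, scfg)
    sets = synth.generate_gene_sets(truth, cfg["synth"].get("n_gene_sets", 20), scfg)
    state.update(train=train, reference=reference, expr=expr, counts=counts,
                 clinical=clinical, truth=truth, edges=edges, gene_sets=sets)
    io.write_expression(train, d / "training_expression.tsv")
    io.write_expression(reference, d / "progenitor_expression.tsv")
    io.write_expression(expr, d / "cohort_expression.tsv")
    io.write_expression(counts, d / "cohort_counts.tsv")
    io.write_clinical(clinical, d / "clinical.tsv")
    io.write_edges(edges, d / "interactions.tsv")
    io.write_gmt(sets, d / "gene_sets.gmt")
    return sorted(d.iterdir())


def _load_inputs(cfg, state):
    inp = cfg["inputs"]
    loaders = {"train": io.read_expression, "reference": io.read_expression,
               "expr": io.read_expression,
               "counts": io.read_expression, "clinical": io.read_clinical,
               "gmt": io.read_gmt, "edges": io.read_edges}
    for key, loader in loaders.items():
        if key not in state and inp.get(key):
            state["gene_sets" if key == "gmt" else key] = loader(inp[key])


def _stage_fit(cfg, state, d: Path):
    _load_inputs(cfg, state)
    sc = cfg["stemness"]
    train = state["train"]
    centering = None
    if state.get("reference") is not None:
        # center on stem + differentiated means so the signature captures the
        # stemness contrast (self-centering collapses the optimum to w = 0)
        combined = pd.concat([train, state["reference"].reindex(train.index)], axis=1)
        centering = combined.mean(axis=1)
    model = stemness.fit_oclr(train, penalty_l2=sc["penalty_l2"],
                              tol=sc["tol"], max_iter=sc["max_iter"],
                              centering=centering)
    state["model"] = model
    model.save(d / "model.tsv")
    return [d / "model.tsv", d / "model.tsv.json"]


def _stage_score(cfg, state, d: Path):
    _load_inputs(cfg, state)
    purity = state["clinical"]["purity"] if "purity" in state.get("clinical", pd.DataFrame()) else None
    scored = stemness.score_cohort(state["model"], state["expr"], purity=purity,
                                   rescale_method=cfg["stemness"]["rescale"])
    state["scored"] = scored
    p = d / "scores.tsv"
    p.parent.mkdir(parents=True, exist_ok=True)
    scored.to_frame().to_csv(p, sep="\t", index_label="sample_id")
    return [p]


def _stage_split(cfg, state, d: Path):
    scored = state["scored"]
    d.mkdir(parents=True, exist_ok=True)
    p = d / "groups.tsv"
    scored.group.rename("group").to_csv(p, sep="\t", index_label="sample_id")
    counts = scored.group.value_counts().to_dict()
    io.write_json({"group_sizes": counts}, d / "group_sizes.json")
    return [p, d / "group_sizes.json"]


def _stage_associate(cfg, state, d: Path):
    scored, clinical = state["scored"], state["clinical"]
    acfg = cfg["associate"]
    rows = []
    for cov in acfg["covariates"]:
        res = association.compare_index_by_covariate(scored.mrnasi, clinical, cov)
        rows.append({"covariate": res.covariate, "test": res.test,
                     "statistic": res.statistic, "p_value": res.p_value})
    outputs = []
    d.mkdir(parents=True, exist_ok=True)
    gt = d / "group_tests.tsv"
    pd.DataFrame(rows).to_csv(gt, sep="\t", index=False)
    outputs.append(gt)
    surv_rows = []
    for name, (tcol, ecol) in acfg["endpoints"].items():
        filt = association.filter_survival(clinical, tcol, ecol)
        shared = filt.index.intersection(scored.group.index)
        grp = scored.group.loc[shared]
        stat, p = association.logrank_test(filt.loc[shared, tcol], filt.loc[shared, ecol], grp)
        surv_rows.append({"endpoint": name, "n": len(shared), "logrank_chi2": stat, "p_value": p})
        for lab in ("H", "L"):
            sel = shared[grp == lab]
            km = association.km_estimate(filt.loc[sel, tcol], filt.loc[sel, ecol])
            kp = d / f"km_{name}_{lab}.tsv"
            km.to_csv(kp, sep="\t", index=False)
            outputs.append(kp)
    sv = d / "survival_tests.tsv"
    pd.DataFrame(surv_rows).to_csv(sv, sep="\t", index=False)
    outputs.append(sv)
    return outputs


def _stage_de(cfg, state, d: Path):
    groups = state["scored"].group
    if cfg["de"]["method"] == "nb":
        table = diffexpr.nb_wald_test(state["counts"], groups,
                                      min_total_count=cfg["de"]["min_total_count"])
    elif cfg["de"]["method"] == "modt":
        table = diffexpr.moderated_t_test(state["expr"], groups)
    else:
        raise ConfigError(f"unknown DE method {cfg['de']['method']!r}; use 'nb' or 'modt'")
    state["degs"] = table
    d.mkdir(parents=True, exist_ok=True)
    p = d / "degs.tsv"
    table.to_csv(p, sep="\t", index_label="gene_id")
    io.write_json({"n_up": table.attrs["n_up"], "n_down": table.attrs["n_down"]},
                  d / "deg_summary.json")
    return [p, d / "deg_summary.json"]


def _stage_enrich(cfg, state, d: Path):
    table = state["degs"]
    query = set(diffexpr.significant_genes(table))
    universe = set(table.index[table["p_value"].notna()])
    results = enrichment.ora_test(query, state["gene_sets"], universe)
    d.mkdir(parents=True, exist_ok=True)
    p = d / "enrichment.tsv"
    enrichment.results_frame(results).to_csv(p, sep="\t", index=False)
    return [p]


def _stage_hubs(cfg, state, d: Path):
    hcfg = cfg["hubs"]
    degs = set(diffexpr.significant_genes(state["degs"]))
    graph = network.read_string_edges(state["edges"], cutoff=hcfg["cutoff"], nodes=degs)
    ranking = network.mcc_rank(graph, top=hcfg["top"], method=hcfg["method"])
    d.mkdir(parents=True, exist_ok=True)
    p = d / "hub_ranking.tsv"
    ranking.to_csv(p, sep="\t")
    outputs = [p]
    hubs = list(ranking.index[ranking["is_hub"]])
    if hubs and "expr" in state and "scored" in state:
        corr = network.correlate_with_index(state["expr"], hubs, state["scored"].mrnasi)
        cp = d / "hub_index_correlation.tsv"
        corr.to_csv(cp, sep="\t")
        outputs.append(cp)
    return outputs


_STAGE_FUNCS = {
    "synth": _stage_synth, "fit": _stage_fit, "score": _stage_score,
    "split": _stage_split, "associate": _stage_associate, "de": _stage_de,
    "enrich": _stage_enrich, "hubs": _stage_hubs,
}
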