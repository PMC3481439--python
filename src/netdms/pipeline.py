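"""End-to-end orchestration of the six analysis stages.

``run_pipeline`` executes gene scoring, network construction, restricted
module search, empirical-null significance, resampling gene-set evaluation
and hypergeometric enrichment in order, writing one output file per stage
plus a JSON manifest (config snapshot, seeds, per-stage output digests,
counts and timings) sufficient to re-run identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import time
from typing import Mapping

from . import formats_io as fio
from . import gene_score, network_build, module_search, significance
from . import gene_set_eval, enrichment
from .errors import ConfigError

log = logging.getLogger("netdms")

DEFAULTS: dict = {
    "method": "all",
    "flank_kb": 50,
    "autosomes_only": True,
    "seed": 0,
    "gene_score": {"n_sims": 1000, "max_sims": 100_000, "fraction": 0.10},
    "search": {"d": 2, "r": 0.1, "min_size": 5},
    "significance": {"alpha": 0.05, "central_fraction": 0.5},
    "evaluate": {"B": 10_000, "p_cut": 0.05, "set_min_size": 5,
                 "set_max_size": 300, "m_total": None},
    "enrich": {"universe": "network"},
}


def _merged(config: Mapping) -> dict:
    out = json.loads(json.dumps(DEFAULTS))
    for key, val in config.items():
        if isinstance(val, Mapping) and isinstance(out.get(key), dict):
            out[key].update(val)
        else:
            out[key] = val
    return out


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def load_config(path: str) -> dict:
    import yaml

    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigError(f"{path}: config must be a YAML mapping")
    return cfg


def run_pipeline(config: Mapping, outdir: str) -> dict:
    """Run all six stages; returns (and writes) the run manifest."""
    from . import __version__

    cfg = _merged(config)
    inputs = cfg.get("inputs") or {}
    required = ["assoc", "loci", "edges", "sets"]
    if cfg["method"] != "minp":
        required.append("geno")
    missing = [k for k in required if not inputs.get(k)]
    if missing:
        raise ConfigError(f"config missing input file(s): {missing}")
    for key in required:
        if not os.path.exists(inputs[key]):
            raise ConfigError(f"input file not found: {inputs[key]}")
    os.makedirs(outdir, exist_ok=True)

    manifest: dict = {
        "tool_version": __version__,
        "config": cfg,
        "seed": cfg["seed"],
        "stages": [],
    }

    def stage(name, fn):
        t0 = time.perf_counter()
        log.info("[%s] started", name)
        outputs, counts = fn()
        elapsed = time.perf_counter() - t0
        digests = {os.path.basename(p): _sha256(p) for p in outputs}
        for key, val in counts.items():
            log.info("[%s] %s=%s", name, key, val)
        manifest["stages"].append(
            {"name": name, "outputs": digests, "counts": counts,
             "seconds": round(elapsed, 3)}
        )

    state: dict = {}

    def run_gene_score():
        assoc, rep = fio.read_assoc(inputs["assoc"])
        loci = fio.read_loci(inputs["loci"])
        geno = (fio.read_genotypes(inputs["geno"])
                if cfg["method"] != "minp" else None)
        scores = gene_score.score_genes(
            assoc, loci, geno, method=cfg["method"],
            flank_bp=int(cfg["flank_kb"]) * 1000,
            autosomes_only=cfg["autosomes_only"],
            fraction=cfg["gene_score"]["fraction"],
            n_sims=cfg["gene_score"]["n_sims"],
            max_sims=cfg["gene_score"]["max_sims"],
            seed=cfg["seed"],
        )
        state.update(assoc=assoc, loci=loci, scores=scores)
        path = os.path.join(outdir, "gene_scores.tsv")
        fio.write_gene_scores(scores, path)
        return [path], {"n_snps_read": len(assoc),
                        "n_snps_rejected": rep.n_rejected,
                        "n_genes_scored": len(scores)}

    def run_network():
        pairs = fio.read_edge_list(inputs["edges"])
        net, rep = network_build.build_network(pairs, state["scores"])
        state["net"] = net
        path = os.path.join(outdir, "network_edges.tsv")
        fio.write_edge_list(sorted(tuple(sorted(e)) for e in net.edges), path)
        summ = network_build.network_summary(net)
        return [path], {"n_nodes": summ["n_nodes"], "n_edges": summ["n_edges"],
                        **{k: v for k, v in rep.items() if k != "n_raw_pairs"}}

    def run_search():
        params = module_search.SearchParams(
            d=int(cfg["search"]["d"]), r=float(cfg["search"]["r"]),
            min_size=int(cfg["search"]["min_size"]),
        )
        modules = module_search.restricted_search(state["net"], params)
        state["modules"] = modules
        path = os.path.join(outdir, "modules_raw.tsv")
        raw = [
            significance.ScoredModule(
                module_id=f"M{i:04d}", seed=m.seed, members=m.members,
                zm=m.zm, zm_centered=float("nan"), zs=float("nan"),
                p_module=float("nan"),
            )
            for i, m in enumerate(
                sorted(modules, key=lambda m: (-m.zm, m.seed)), start=1
            )
        ]
        fio.write_modules(raw, path)
        return [path], {"n_modules": len(modules)}

    def run_significance():
        scores = [m.zm for m in state["modules"]]
        if len(scores) >= significance.MIN_SCORES:
            fit = significance.fit_empirical_null(
                scores, cfg["significance"]["central_fraction"]
            )
        else:
            log.warning(
                "[significance] only %d modules; falling back to the exact "
                "standard-normal null", len(scores),
            )
            fit = significance.exact_null_fit(scores) if scores else None
        stats_list = (significance.module_pvalues(state["modules"], fit)
                      if fit else [])
        selected, pooled = significance.select_significant(
            stats_list, cfg["significance"]["alpha"]
        )
        state.update(stats_list=stats_list, pooled=pooled)
        mod_path = os.path.join(outdir, "modules.tsv")
        fio.write_modules(stats_list, mod_path)
        gmt_path = os.path.join(outdir, "module_genes.gmt")
        sets = []
        if pooled:
            sets.append(fio.GeneSet("module_genes", "pooled significant-module "
                                    "genes", frozenset(pooled)))
        fio.write_gmt(sets, gmt_path)
        counts = {"n_modules_scored": len(stats_list),
                  "n_significant_modules": len(selected),
                  "n_module_genes": len(pooled)}
        if fit:
            counts.update(null_delta=round(fit.delta, 6),
                          null_sigma=round(fit.sigma, 6))
        return [mod_path, gmt_path], counts

    def run_evaluate():
        sets = fio.read_gmt(inputs["sets"])
        sets = gene_set_eval.filter_gene_sets(
            sets, cfg["evaluate"]["set_min_size"], cfg["evaluate"]["set_max_size"]
        )
        if state["pooled"]:
            sets = sets + [fio.GeneSet("module_genes", "pooled",
                                       frozenset(state["pooled"]))]
        snp_map = gene_score.map_snps_to_genes(
            state["assoc"], state["loci"], int(cfg["flank_kb"]) * 1000,
            cfg["autosomes_only"],
        )
        path = os.path.join(outdir, "gene_set_eval.tsv")
        if sets:
            df = gene_set_eval.evaluate_gene_sets(
                state["assoc"], snp_map, sets, B=int(cfg["evaluate"]["B"]),
                p_cut=cfg["evaluate"]["p_cut"],
                m_total=cfg["evaluate"]["m_total"], seed=cfg["seed"],
            )
        else:
            import pandas as pd

            df = pd.DataFrame(columns=["set", "size", "real_count", "p", "p_bh"])
        df.to_csv(path, sep="\t", index=False,
                  float_format="%.6g")
        return [path], {"n_sets_tested": len(sets)}

    def run_enrich():
        sets = fio.read_gmt(inputs["sets"])
        if cfg["enrich"]["universe"] == "network":
            universe = set(state["net"].nodes)
        else:
            universe = set(state["scores"]["gene_id"])
        module_genes = state["pooled"] & universe
        path = os.path.join(outdir, "enrichment.tsv")
        df = enrichment.enrich_all(module_genes, sets, universe)
        df.to_csv(path, sep="\t", index=False, float_format="%.6g")
        return [path], {"n_sets_tested": len(sets),
                        "universe_size": len(universe)}

    stage("gene_score", run_gene_score)
    stage("network_build", run_network)
    stage("module_search", run_search)
    stage("significance", run_significance)
    stage("gene_set_eval", run_evaluate)
    stage("enrichment", run_enrich)

    manifest_path = os.path.join(outdir, "manifest.json")
    tmp = manifest_path + ".tmp"
    with open(tmp, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    os.replace(tmp, manifest_path)
    return manifest
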