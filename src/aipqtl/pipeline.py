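"""Configuration-driven pipeline runs binding the analysis stages together.

A run is described by a single YAML/JSON-style mapping validated against an
explicit schema (unknown keys are rejected so typos fail loudly). Stages
execute in dependency order; each stage writes its outputs into the run
directory and a manifest records the package version, per-stage seeds, and
SHA-256 digests of every input and output table, so that a rerun with the
same config is byte-identical and verifiable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, candidates as cand_mod, expression as expr_mod
from . import io as aio
from . import network as net_mod
from . import quantgen, simulate, xqtl

logger = logging.getLogger("aipqtl.pipeline")

__all__ = ["RunConfig", "run_pipeline", "STAGE_ORDER"]

STAGE_ORDER = ["simulate", "quantgen", "xqtl", "candidates", "network", "expression"]

_SCHEMA: dict[str, set] = {
    "": {"seed", "stages"},
    "simulate": {
        "n_founders", "n_sites_per_chrom", "chromosomes", "private_fraction",
        "base_size", "generations", "scored_flies", "select_fraction",
        "mean_depth", "qtl", "grand_mean", "residual_sd", "sex", "exposure",
    },
    "quantgen": {
        "elutions", "crossed_factor", "sigma2_L", "sigma2_LxF", "sigma2_Rep",
        "sigma2_eps", "n_lines", "n_reps", "n_flies_per_rep",
    },
    "xqtl": {"counts", "n_per_pool", "alpha", "nominal_threshold"},
    "candidates": {"sets", "universe", "B", "min_analyses"},
    "network": {"edges", "candidate_list", "edge_type", "allow_missing"},
    "expression": {"ct_table", "candidate_genes", "reference", "alpha"},
}


class RunConfig:
    """Validated pipeline configuration."""

    def __init__(self, raw: dict):
        unknown = set(raw) - _SCHEMA[""] - set(STAGE_ORDER)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        stages = raw.get("stages") or [s for s in STAGE_ORDER if s in raw]
        bad = [s for s in stages if s not in STAGE_ORDER]
        if bad:
            raise ValueError(f"unknown stages: {bad}")
        for stage in stages:
            params = raw.get(stage, {}) or {}
            unknown = set(params) - _SCHEMA[stage]
            if unknown:
                raise ValueError(f"unknown keys in stage {stage!r}: {sorted(unknown)}")
        if "seed" not in raw:
            raise ValueError("config must set an explicit top-level seed")
        self.seed = int(raw["seed"])
        self.stages = [s for s in STAGE_ORDER if s in stages]
        self.params = {s: (raw.get(s, {}) or {}) for s in self.stages}

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        import yaml

        with open(path) as fh:
            return cls(yaml.safe_load(fh))

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage substream of the master seed (< 2**31)."""
        h = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(h[:4], "big") % (2**31)


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig, out_dir: str) -> dict:
    """Execute the configured stages; returns the manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "seed": config.seed, "stages": {}}
    artifacts: dict[str, Path] = {}

    for stage in config.stages:
        params = config.params[stage]
        seed = config.stage_seed(stage)
        logger.info("stage %s (seed %d)", stage, seed)
        record: dict = {"seed": seed, "params": {k: v for k, v in params.items()}}
        runner = _RUNNERS[stage]
        outputs = runner(params, seed, out, artifacts)
        record["outputs"] = {name: _digest(path) for name, path in outputs.items()}
        artifacts.update(outputs)
        manifest["stages"][stage] = record

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest


def _require(artifacts: dict, params: dict, key: str, artifact: str, stage: str):
    """Resolve a stage input from config path or an upstream artifact."""
    if params.get(key):
        return Path(params[key])
    if artifact in artifacts:
        return artifacts[artifact]
    raise ValueError(
        f"stage {stage!r} needs {key!r} (no path configured and no upstream "
        f"stage produced {artifact!r})"
    )


def _run_simulate(params, seed, out, artifacts):
    chroms = params.get("chromosomes")
    if chroms:
        chroms = {c: tuple(v) for c, v in chroms.items()}
    else:
        chroms = {"2L": simulate.DEFAULT_CHROMOSOMES["2L"]}
    panel = simulate.make_founder_panel(
        n_lines=params.get("n_founders", 6),
        n_sites_per_chrom=params.get("n_sites_per_chrom", 200),
        private_fraction=params.get("private_fraction", 0.3),
        seed=seed,
        chromosomes=chroms,
    )
    base = simulate.diallel_base_population(panel, params.get("base_size", 300), seed + 1)
    scored = params.get("scored_flies", 600)
    pop = simulate.advance_generations(
        base, params.get("generations", 25), panel, seed + 2, final_size=scored
    )
    qtl = {int(q["site"]): float(q["effect"]) for q in params.get("qtl", [])}
    model = simulate.PhenotypeModel(
        grand_mean=params.get("grand_mean", 6.0),
        qtl_effects=qtl,
        residual_sd=params.get("residual_sd", 1.0),
    )
    elut = simulate.simulate_elution(
        pop, model, params.get("sex", "F"), params.get("exposure", "E1"),
        n_flies=scored, seed=seed + 3, panel=panel,
    )
    sens, res = xqtl.select_extremes(elut, params.get("select_fraction", 0.10), seed + 4)
    fly_idx = elut["id"].str.removeprefix("ind").astype(int).to_numpy()
    counts = simulate.simulate_pool_seq(
        pop, (fly_idx[sens], fly_idx[res]), panel,
        mean_depth=params.get("mean_depth", 50.0), seed=seed + 5,
    )
    paths = {
        "panel_vcf": out / "founders.vcf",
        "elutions": out / "elutions.tsv",
        "pool_counts": out / "pool_counts.tsv",
    }
    aio.write_panel_vcf(panel, paths["panel_vcf"])
    aio.write_table(elut, paths["elutions"])
    aio.write_table(counts, paths["pool_counts"])
    paths["_pool_size"] = _write_json(out / "pool_size.json", {"pool_size": int(len(sens))})
    return paths


def _write_json(path: Path, obj) -> Path:
    path.write_text(json.dumps(obj, indent=2, default=str))
    return path


def _run_quantgen(params, seed, out, artifacts):
    if params.get("elutions"):
        df = aio.read_table(params["elutions"], ["line", "replicate", "minutes"])
        factor = params.get("crossed_factor", "sex")
    else:
        spec = simulate.VarCompSpec(
            sigma2_L=params.get("sigma2_L", 3.0),
            sigma2_LxF=params.get("sigma2_LxF", 0.5),
            sigma2_Rep=params.get("sigma2_Rep", 0.5),
            sigma2_eps=params.get("sigma2_eps", 4.83),
            n_lines=params.get("n_lines", 50),
            n_reps=params.get("n_reps", 2),
            n_flies_per_rep=params.get("n_flies_per_rep", 70),
        )
        df = simulate.simulate_dgrp_fly_data(spec, seed)
        factor = "sex"
    vc = quantgen.partition_variance(df, crossed_factor=factor)
    result = {
        "sigma2_L": vc.sigma2_L, "sigma2_LxF": vc.sigma2_LxF,
        "sigma2_Rep": vc.sigma2_Rep, "sigma2_eps": vc.sigma2_eps,
        "sigma2_G": vc.sigma2_G, "sigma2_P": vc.sigma2_P, "H2": vc.H2,
    }
    paths = {"varcomp": _write_json(out / "varcomp.json", result),
             "anova": out / "varcomp_anova.tsv"}
    aio.write_table(vc.anova, paths["anova"])
    return paths


def _run_xqtl(params, seed, out, artifacts):
    counts_path = _require(artifacts, params, "counts", "pool_counts", "xqtl")
    counts = aio.read_table(counts_path, aio.POOL_COLUMNS)
    n = params.get("n_per_pool")
    if n is None:
        size_file = artifacts.get("_pool_size")
        if size_file is None:
            raise ValueError("stage 'xqtl' needs n_per_pool when counts come from a file")
        n = 2 * json.loads(Path(size_file).read_text())["pool_size"]
    res = xqtl.run_xqtl(counts, n, alpha=params.get("alpha", 0.05),
                        nominal_threshold=params.get("nominal_threshold", 1e-5))
    paths = {"xqtl_results": out / "xqtl_results.tsv"}
    aio.write_table(res, paths["xqtl_results"])
    paths["xqtl_summary"] = _write_json(out / "xqtl_summary.json", {
        "n_tests": int(res.attrs["n_tests"]),
        "bonferroni_threshold": res.attrs["bonferroni_threshold"],
        "n_bonferroni": int(res["sig_bonferroni"].sum()),
        "n_nominal": int(res["sig_nominal"].sum()),
    })
    return paths


def _run_candidates(params, seed, out, artifacts):
    sets_df = aio.read_table(_require(artifacts, params, "sets", "candidate_sets",
                                      "candidates"), ["analysis", "gene"])
    sets = {a: set(g["gene"]) for a, g in sets_df.groupby("analysis")}
    if params.get("universe"):
        universe = set(pd.read_csv(params["universe"], sep="\t")["gene"])
    else:
        universe = set().union(*sets.values())
    res = cand_mod.overlap_permutation_test(
        sets, universe, B=params.get("B", 1000), seed=seed,
        min_analyses=params.get("min_analyses", 2),
    )
    return {"overlap": _write_json(out / "overlap.json", {
        "observed": res["observed"], "p_value": res["p_value"],
        "B": res["B"], "genes": res["genes"],
    })}


def _run_network(params, seed, out, artifacts):
    edges = aio.read_edge_list(_require(artifacts, params, "edges", "edge_list",
                                        "network"))
    cand = set(pd.read_csv(params["candidate_list"], sep="\t")["gene"])
    g = net_mod.graph_from_edges(edges, edge_type=params.get("edge_type"))
    sub = net_mod.extract_subnetwork(g, cand, allow_missing=params.get("allow_missing", 1))
    summary = net_mod.summarize_network(sub, cand)
    paths = {"subnetwork_graphml": out / "subnetwork.graphml",
             "network_summary": _write_json(out / "network_summary.json", summary)}
    aio.write_graphml(sub, paths["subnetwork_graphml"])
    return paths


def _run_expression(params, seed, out, artifacts):
    ct = aio.read_table(_require(artifacts, params, "ct_table", "ct_table",
                                 "expression"), aio.CT_COLUMNS)
    dct = expr_mod.delta_ct(ct, reference=params.get("reference", "Gpdh"))
    results = expr_mod.pool_ttest_all(dct)
    paths = {"expression_results": out / "expression_results.tsv"}
    aio.write_table(results, paths["expression_results"])
    if params.get("candidate_genes"):
        cand_genes = set(pd.read_csv(params["candidate_genes"], sep="\t")["gene"])
        is_cand = results["gene"].isin(cand_genes)
        fisher = expr_mod.altered_proportion_test(
            results[is_cand], results[~is_cand], alpha=params.get("alpha", 0.05)
        )
        paths["fisher"] = _write_json(out / "expression_fisher.json", {
            "table": fisher["table"].tolist(), "p_value": fisher["p_value"],
            "prop_candidate": fisher["prop_candidate"],
            "prop_random": fisher["prop_random"],
        })
    return paths


_RUNNERS = {
    "simulate": _run_simulate,
    "quantgen": _run_quantgen,
    "xqtl": _run_xqtl,
    "candidates": _run_candidates,
    "network": _run_network,
    "expression": _run_expression,
}
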