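"""End-to-end orchestration: one config in, a run directory of artifacts out.

Stages: genotype filtering -> diversity/FST -> geographic, resistance and
environmental distances -> Mantel and reciprocal causal modeling -> GDM fit,
importance and splines -> MLPE ranking -> genomic offset (when future climate
layers exist). Every table/matrix/raster is written as plain text and listed
with a SHA-256 checksum in ``manifest.json``; identical config + seed
reproduces identical checksums.

The config is a YAML mapping with exactly one of a ``synthetic`` block
(generator settings) or an ``inputs`` block (paths to VCF, per-individual
population/coordinate TSV, per-population environment TSV, suitability
raster, optional future climate rasters).
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import association, distances, gdm, genotype, mlpe, offset, synthetic
from .core import PairwiseMatrix
from .rasters import Grid, read_ascii_grid, write_ascii_grid

logger = logging.getLogger(__name__)

__all__ = ["load_config", "run_pipeline"]


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_matrix(pm: PairwiseMatrix, path: Path) -> None:
    pm.to_csv(path)


class _Run:
    """Bookkeeping for one pipeline execution."""

    def __init__(self, outdir: Path):
        self.outdir = outdir
        outdir.mkdir(parents=True, exist_ok=True)
        self.files: list[str] = []
        self.stages: list[str] = []

    def record(self, *paths: Path) -> None:
        self.files.extend(str(p.relative_to(self.outdir)) for p in paths)

    def stage_done(self, name: str) -> None:
        self.stages.append(name)
        logger.info("stage complete: %s", name)


def _synthetic_inputs(cfg: dict, run: _Run):
    sc = synthetic.SyntheticConfig(**{
        k: (tuple(v) if k in ("grid_shape", "env_names") else v)
        for k, v in cfg.items()
    })
    env_rasters, suit = synthetic.generate_env_rasters(sc)
    pops = synthetic.place_populations(sc, suit)
    env_values = synthetic.extract_env_values(pops, env_rasters)
    truth = synthetic.simulate_allele_frequencies(pops, env_values, sc)
    gm = synthetic.simulate_genotypes(truth, sc)
    assignment = synthetic.population_assignment(truth, sc)
    future = synthetic.future_env_rasters(env_rasters)

    d = run.outdir
    vcf_path = d / "genotypes.vcf"
    genotype.write_vcf(gm, vcf_path)
    ind_rows = [
        {"individual": ind, "pop_id": p, "x": pops.loc[p, "x"], "y": pops.loc[p, "y"]}
        for ind, p in assignment.items()
    ]
    pd.DataFrame(ind_rows).to_csv(d / "populations.tsv", sep="\t", index=False)
    env_values.to_csv(d / "environment.tsv", sep="\t", index_label="pop_id")
    write_ascii_grid(suit, d / "suitability.asc")
    raster_paths = []
    for name, g in env_rasters.items():
        p = d / f"env_current_{name}.asc"
        write_ascii_grid(g, p)
        raster_paths.append(p)
    for name, g in future.items():
        p = d / f"env_future_{name}.asc"
        write_ascii_grid(g, p)
        raster_paths.append(p)
    run.record(vcf_path, d / "populations.tsv", d / "environment.tsv",
               d / "suitability.asc", *raster_paths)
    # read back through the standard path so real and synthetic runs share it
    gm = genotype.read_vcf(vcf_path)
    return gm, assignment, pops, env_values, suit, env_rasters, future


def _real_inputs(cfg: dict, run: _Run):
    gm = genotype.read_vcf(cfg["vcf"])
    ind = pd.read_csv(cfg["populations"], sep="\t", dtype={"pop_id": str})
    assignment = dict(zip(ind["individual"].astype(str), ind["pop_id"].astype(str)))
    pops = (
        ind.groupby("pop_id", sort=False)[["x", "y"]].first()
    )
    env_values = pd.read_csv(cfg["env"], sep="\t", index_col="pop_id")
    env_values.index = env_values.index.astype(str)
    suit = read_ascii_grid(cfg["suitability"]) if "suitability" in cfg else None
    current = {
        name: read_ascii_grid(p) for name, p in cfg.get("current_env", {}).items()
    }
    future = {
        name: read_ascii_grid(p) for name, p in cfg.get("future_env", {}).items()
    }
    if suit is not None and "row" not in pops.columns:
        rc = [suit.snap(x, y) for x, y in pops[["x", "y"]].to_numpy()]
        pops["row"] = [r for r, _ in rc]
        pops["col"] = [c for _, c in rc]
    return gm, assignment, pops, env_values, suit, current, future


def run_pipeline(config: dict | str | Path, outdir: str | Path | None = None) -> Path:
    """Execute the full analysis; returns the run directory."""
    if not isinstance(config, dict):
        config = load_config(config)
    out = Path(outdir if outdir is not None else config.get("output", "landgen-run"))
    run = _Run(out)
    seed = int(config.get("seed", 0))
    has_synth = "synthetic" in config
    has_real = "inputs" in config
    if has_synth == has_real:
        raise ValueError("config must contain exactly one of 'synthetic' or 'inputs'")

    stage = "inputs"
    try:
        if has_synth:
            scfg = dict(config["synthetic"])
            scfg.setdefault("seed", seed)
            (gm, assignment, pops, env_values, suit,
             current_env, future_env) = _synthetic_inputs(scfg, run)
        else:
            (gm, assignment, pops, env_values, suit,
             current_env, future_env) = _real_inputs(config["inputs"], run)
        run.stage_done(stage)

        stage = "filter"
        fcfg = config.get("filters", {})
        gm = genotype.filter_snps(
            gm,
            min_qual=fcfg.get("min_qual", 30.0),
            min_maf=fcfg.get("min_maf", 0.01),
            min_call_rate=fcfg.get("min_call_rate", 0.7),
        )
        (out / "filter_attrition.json").write_text(json.dumps(gm.attrition, indent=2))
        run.record(out / "filter_attrition.json")
        run.stage_done(stage)

        stage = "diversity"
        div = genotype.population_diversity(gm, assignment)
        div.to_csv(out / "diversity.tsv", sep="\t")
        chi2 = genotype.ho_he_chi2(gm, assignment)
        chi2.to_csv(out / "hwe_chi2.tsv", sep="\t")
        corr = genotype.diversity_env_correlation(div, env_values)
        corr.to_csv(out / "diversity_env_correlation.tsv", sep="\t", index=False)
        run.record(out / "diversity.tsv", out / "hwe_chi2.tsv",
                   out / "diversity_env_correlation.tsv")
        run.stage_done(stage)

        stage = "fst"
        G = genotype.fst_matrix(gm, assignment, statistic="weighted")
        _write_matrix(G, out / "fst_weighted.csv")
        run.record(out / "fst_weighted.csv")
        run.stage_done(stage)

        stage = "distances"
        pops = pops.loc[G.labels]
        env_values = env_values.loc[G.labels]
        geo_mode = config.get("distances", {}).get("mode", "planar")
        euclid = distances.euclidean_matrix(pops, mode=geo_mode)
        _write_matrix(euclid, out / "dist_euclidean.csv")
        var_matrices: dict[str, PairwiseMatrix] = {"Euclidean": euclid}
        if suit is not None:
            rcfg = config.get("resistance", {})
            rr = distances.suitability_to_resistance(
                suit, method=rcfg.get("method", "conductance"),
                epsilon=rcfg.get("epsilon", 1e-3),
            )
            lcd = distances.least_cost_distance(rr, pops)
            cd = distances.circuit_distance(rr, pops)
            _write_matrix(lcd, out / "dist_lcd.csv")
            _write_matrix(cd, out / "dist_cd.csv")
            var_matrices["LCD"] = lcd
            var_matrices["CD"] = cd
            run.record(out / "dist_lcd.csv", out / "dist_cd.csv")
        env_mats = distances.env_distance_matrices(env_values)
        for name, pm in env_mats.items():
            _write_matrix(pm, out / f"dist_env_{name}.csv")
            run.record(out / f"dist_env_{name}.csv")
            var_matrices[name] = pm
        run.record(out / "dist_euclidean.csv")
        run.stage_done(stage)

        stage = "mantel"
        tcfg = config.get("tests", {})
        n_perm = int(tcfg.get("n_perm", 999))
        method = tcfg.get("method", "spearman")
        ss = np.random.SeedSequence([seed, 1])
        mantel_seeds = iter(int(s % 2**31) for s in ss.generate_state(len(var_matrices)))
        rows = []
        for name, pm in var_matrices.items():
            res = association.mantel(G, pm, n_perm=n_perm, method=method,
                                     seed=next(mantel_seeds))
            rows.append({"variable": name, "r": res.r, "p": res.p,
                         "n_perm": res.n_perm, "method": res.method,
                         "note": res.note})
        pd.DataFrame(rows).to_csv(out / "mantel_tests.tsv", sep="\t", index=False)
        heat = association.rcm_heatmap(G, var_matrices, n_perm=n_perm,
                                       method=method, seed=seed + 2)
        for name, arr in (("difference", heat.difference), ("rpm", heat.rpm),
                          ("pvalues", heat.pvals)):
            pd.DataFrame(arr, index=heat.variables, columns=heat.variables).to_csv(
                out / f"rcm_{name}.csv"
            )
            run.record(out / f"rcm_{name}.csv")
        run.record(out / "mantel_tests.tsv")
        run.stage_done(stage)

        stage = "gdm"
        gcfg = config.get("gdm", {})
        pairs = gdm.build_site_pairs(G, env_values, coords=pops,
                                     include_geo=True, geo_matrix=euclid)
        model = gdm.fit_gdm(pairs, n_splines=int(gcfg.get("n_splines", 3)))
        summary = {
            "intercept": model.intercept,
            "coefficients": {k: v.tolist() for k, v in model.coefficients.items()},
            "knots": {k: b.knots.tolist() for k, b in model.bases.items()},
            "deviance": model.deviance,
            "null_deviance": model.null_deviance,
            "percent_deviance_explained": gdm.percent_deviance_explained(model),
            "converged": model.converged,
            "n_iter": model.n_iter,
        }
        (out / "gdm_summary.json").write_text(json.dumps(summary, indent=2))
        gdm.predictor_importance(model).to_csv(out / "gdm_importance.tsv",
                                               sep="\t", index=False)
        gdm.evaluate_splines(model).to_csv(out / "gdm_splines.tsv",
                                           sep="\t", index=False)
        resid = pd.DataFrame({
            "pop_a": [a for a, _ in pairs.pair_labels],
            "pop_b": [b for _, b in pairs.pair_labels],
            "observed": pairs.response,
            "predicted": model.predict(pairs),
        })
        resid["residual"] = resid["observed"] - resid["predicted"]
        resid.to_csv(out / "gdm_residuals.tsv", sep="\t", index=False)
        run.record(out / "gdm_summary.json", out / "gdm_importance.tsv",
                   out / "gdm_splines.tsv", out / "gdm_residuals.tsv")
        run.stage_done(stage)

        stage = "mlpe"
        ranking = mlpe.rank_mlpe(G, var_matrices)
        ranking.to_csv(out / "mlpe_ranking.tsv", sep="\t", index=False)
        run.record(out / "mlpe_ranking.tsv")
        run.stage_done(stage)

        if future_env:
            stage = "offset"
            climate = [p for p in model.predictors
                       if p != gdm.GEO_NAME and p in current_env and p in future_env]
            cur = offset.ClimateStack(
                layers={k: current_env[k] for k in climate}, scenario="current")
            fut = offset.ClimateStack(
                layers={k: future_env[k] for k in climate}, scenario="future")
            off = offset.genomic_offset(model, cur, fut)
            write_ascii_grid(off.offset, out / "offset.asc")
            write_ascii_grid(off.eta, out / "offset_eta.asc")
            off.at(pops).to_csv(out / "offset_populations.tsv", sep="\t")
            run.record(out / "offset.asc", out / "offset_eta.asc",
                       out / "offset_populations.tsv")
            run.stage_done(stage)
    except Exception as err:
        manifest = {"seed": seed, "config": _jsonable(config),
                    "stages_completed": run.stages, "failed_stage": stage,
                    "error": str(err)}
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {err}") from err

    manifest = {
        "seed": seed,
        "config": _jsonable(config),
        "stages_completed": run.stages,
        "files": {f: _sha256(out / f) for f in sorted(run.files)},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    if isinstance(obj, Path):
        return str(obj)
    return obj
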