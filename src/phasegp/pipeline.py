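"""End-to-end analysis pipeline: filter -> impute -> fit/CV across models
and marker sets -> model comparison -> saturation/chip design -> GEBV
ranking, driven by one configuration mapping and with content-hash stage
caching so reruns skip unchanged work.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import chip as chip_mod
from .data import GenotypeMatrix, PhenotypeTable
from .evaluate import cross_validate
from .impute import impute
from .io import filter_matrix, read_genotypes, read_phenotypes, write_genotypes
from .models import ModelConfig, fit
from .ranking import RankingTable, multi_trait_elites, recommendation_domains
from .simulate import SimConfig, TraitSpec, simulate_genotypes, simulate_phenotypes
from .stats import dunn_posthoc, kruskal_wallis

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline", "DEFAULT_CONFIG"]

DEFAULT_CONFIG: dict[str, Any] = {
    "genotypes": None,          # path, or None when "synthetic" is given
    "phenotypes": None,
    "synthetic": None,          # mapping of SimConfig overrides
    "traits": None,             # default: all traits in the phenotype table
    "localities": None,
    "models": ["BRR", "BL", "BayesA", "BayesB", "BayesC", "RKHS"],
    "marker_sets": {"all": None},   # name -> None | path of marker IDs
    "seeds": [0, 1234, 2023],
    "n_folds": 5,
    "n_iter": 1500,
    "burn_in": 300,
    "thin": 5,
    "filter": {},
    "impute": {},
    "chip": {"grid": None, "size": 500, "delta": 0.02, "enabled": True},
    "top_k": 10,
}


def _hash_obj(*parts: Any) -> str:
    h = hashlib.sha256()
    for p in parts:
        if isinstance(p, Path):
            h.update(p.read_bytes())
        else:
            h.update(json.dumps(p, sort_keys=True, default=str).encode())
    return h.hexdigest()[:16]


class _Stages:
    """Manifest-backed stage cache keyed by content hashes."""

    def __init__(self, outdir: Path):
        self.outdir = outdir
        self.path = outdir / "manifest.json"
        self.manifest = (json.loads(self.path.read_text())
                         if self.path.exists() else {})
        self.status: dict[str, str] = {}

    def fresh(self, stage: str, key: str, outputs: list[Path]) -> bool:
        ok = (self.manifest.get(stage) == key
              and all(p.exists() for p in outputs))
        self.status[stage] = "cached" if ok else "run"
        if ok:
            logger.info("stage %s: cached", stage)
        return ok

    def done(self, stage: str, key: str) -> None:
        self.manifest[stage] = key
        self.path.write_text(json.dumps(self.manifest, indent=2))


def _load_inputs(config: dict, outdir: Path
                 ) -> tuple[GenotypeMatrix, PhenotypeTable]:
    if config.get("synthetic") is not None:
        sim_kwargs = dict(config["synthetic"])
        traits = sim_kwargs.pop("traits", None)
        if traits is not None:
            sim_kwargs["traits"] = tuple(TraitSpec(**t) for t in traits)
        sim = SimConfig(**sim_kwargs)
        geno = simulate_genotypes(sim)
        complete = geno
        if sim.missing_rate > 0:
            # phenotypes need the complete matrix; mask only the exported one
            sim0 = SimConfig(**{**sim.__dict__, "missing_rate": 0.0})
            complete = simulate_genotypes(sim0)
        pheno, _ = simulate_phenotypes(complete, sim)
        return geno, pheno
    if not config.get("genotypes") or not config.get("phenotypes"):
        raise ValueError(
            "config must give 'genotypes' and 'phenotypes' paths or a "
            "'synthetic' section")
    return (read_genotypes(config["genotypes"]),
            read_phenotypes(config["phenotypes"]))


def run_pipeline(config: dict[str, Any], outdir: str | Path) -> dict[str, Any]:
    """Run the full analysis described by ``config`` into ``outdir``.

    Stages are cached: when a stage's inputs (upstream artifacts plus the
    relevant configuration subset) are unchanged and its outputs exist, it
    is skipped and reported as ``"cached"`` in the returned status map.

    Returns a mapping with artifact paths, per-stage status and the summary
    table.
    """
    cfg = {**DEFAULT_CONFIG, **config}
    cfg["chip"] = {**DEFAULT_CONFIG["chip"], **(config.get("chip") or {})}
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages = _Stages(outdir)
    artifacts: dict[str, Any] = {}

    # ---- load + filter + impute -------------------------------------
    geno, pheno = _load_inputs(cfg, outdir)
    pheno.check_against(geno)
    prep_key = _hash_obj(
        {k: cfg[k] for k in ("genotypes", "phenotypes", "synthetic",
                             "filter", "impute")},
        geno.dosages.tobytes().hex()[:64], pheno.records.to_json())
    imputed_path = outdir / "imputed.vcf"
    report_path = outdir / "filter_report.json"
    if not stages.fresh("prepare", prep_key, [imputed_path, report_path]):
        filtered, report = filter_matrix(geno, **(cfg["filter"] or {}))
        report.to_json(report_path)
        if filtered.missing_mask().any():
            filtered = impute(filtered, **(cfg["impute"] or {}))
        write_genotypes(filtered, imputed_path, format="vcf")
        stages.done("prepare", prep_key)
    geno_i = read_genotypes(imputed_path)
    artifacts["imputed"] = imputed_path
    artifacts["filter_report"] = report_path

    traits = cfg["traits"] or pheno.traits
    localities = cfg["localities"] or pheno.localities
    means = pheno.genotype_means()
    combos = [
        (t, l) for t in traits for l in localities
        if not means[(means["trait"] == t) & (means["locality"] == l)].empty
    ]

    marker_sets: dict[str, np.ndarray | None] = {}
    for name, spec in (cfg["marker_sets"] or {"all": None}).items():
        if spec is None:
            marker_sets[name] = None
        else:
            ids = [ln.strip() for ln in Path(spec).read_text().splitlines()
                   if ln.strip()]
            lookup = {mid: j for j, mid in enumerate(geno_i.marker_ids)}
            marker_sets[name] = np.array(
                [lookup[i] for i in ids if i in lookup], dtype=np.intp)

    def trait_xy(trait: str, loc: str) -> tuple[np.ndarray, np.ndarray, list[str]]:
        sub = means[(means["trait"] == trait) & (means["locality"] == loc)]
        ids = [g for g in geno_i.samples if g in set(sub["genotype_id"])]
        idx = [geno_i.samples.index(g) for g in ids]
        y = pheno.trait_vector(trait, loc, ids)
        return geno_i.dosages[idx].astype(float), y, ids

    mcmc = {"n_iter": cfg["n_iter"], "burn_in": cfg["burn_in"],
            "thin": cfg["thin"]}

    # ---- cross-validation over models x marker sets ------------------
    cv_key = _hash_obj(stages.manifest.get("prepare"), mcmc, cfg["models"],
                       cfg["seeds"], cfg["n_folds"], traits, localities,
                       sorted(cfg["marker_sets"] or {}))
    cv_path = outdir / "cv.tsv"
    if not stages.fresh("cv", cv_key, [cv_path]):
        rows = []
        for trait, loc in combos:
            X, y, _ = trait_xy(trait, loc)
            for set_name, subset in marker_sets.items():
                for model in cfg["models"]:
                    for seed in cfg["seeds"]:
                        mc = ModelConfig(model=model, seed=int(seed), **mcmc)
                        cv = cross_validate(X, y, mc, n_folds=cfg["n_folds"],
                                            seed=int(seed),
                                            marker_subset=subset)
                        f = cv.folds.assign(trait=trait, locality=loc,
                                            model=model, marker_set=set_name,
                                            seed=seed)
                        rows.append(f)
        pd.concat(rows, ignore_index=True).to_csv(cv_path, sep="\t",
                                                  index=False)
        stages.done("cv", cv_key)
    cv_df = pd.read_csv(cv_path, sep="\t")
    artifacts["cv"] = cv_path

    # ---- model comparison (Kruskal-Wallis + Dunn/Bonferroni) ---------
    cmp_key = _hash_obj(stages.manifest.get("cv"))
    cmp_path = outdir / "comparison.tsv"
    if not stages.fresh("compare", cmp_key, [cmp_path]):
        rows = []
        for (trait, loc, mset), sub in cv_df.groupby(
                ["trait", "locality", "marker_set"]):
            models = sorted(sub["model"].unique())
            if len(models) < 2:
                continue
            groups = [sub.loc[sub["model"] == m, "r_y"].dropna().to_numpy()
                      for m in models]
            if any(g.size < 2 for g in groups):
                continue
            H, p = kruskal_wallis(groups)
            dunn = dunn_posthoc(groups)
            for i, mi in enumerate(models):
                for j in range(i + 1, len(models)):
                    rows.append({"trait": trait, "locality": loc,
                                 "marker_set": mset, "kruskal_H": H,
                                 "kruskal_p": p, "model_a": mi,
                                 "model_b": models[j],
                                 "dunn_p_bonf": dunn.iloc[i, j]})
        pd.DataFrame(rows).to_csv(cmp_path, sep="\t", index=False)
        stages.done("compare", cmp_key)
    artifacts["comparison"] = cmp_path

    # ---- summary (best model per trait x locality x marker set) ------
    summary = (
        cv_df.groupby(["trait", "locality", "marker_set", "model"])
        .agg(r_y_median=("r_y", "median"), r_y_sd=("r_y", "std"),
             h2_g=("h2_g", "mean"), mse_test=("mse_test", "mean"))
        .reset_index()
    )
    best = (summary.sort_values(
        ["r_y_median", "mse_test"], ascending=[False, True])
        .groupby(["trait", "locality", "marker_set"]).head(1)
        .rename(columns={"model": "best_model"}))
    summary_path = outdir / "summary.tsv"
    best.to_csv(summary_path, sep="\t", index=False)
    (outdir / "summary.md").write_text(best.to_markdown(index=False))
    artifacts["summary"] = summary_path

    # ---- final fits, chips and GEBV ranking --------------------------
    rank_key = _hash_obj(stages.manifest.get("cv"), cfg["top_k"],
                         cfg["chip"])
    rank_path = outdir / "ranking.tsv"
    rec_path = outdir / "recommendations.json"
    overlap_path = outdir / "chip_overlap.json"
    chip_enabled = cfg["chip"].get("enabled", True)
    targets = [rank_path, rec_path] + ([overlap_path] if chip_enabled else [])
    if not stages.fresh("rank", rank_key, targets):
        tables: list[RankingTable] = []
        panels: list[chip_mod.ChipPanel] = []
        rank_rows = []
        for trait, loc in combos:
            X, y, ids = trait_xy(trait, loc)
            row = best[(best["trait"] == trait) & (best["locality"] == loc)
                       & (best["marker_set"] == list(marker_sets)[0])]
            model = row["best_model"].iloc[0] if not row.empty else "BayesC"
            mc = ModelConfig(model=model, seed=int(cfg["seeds"][0]), **mcmc)
            summ = fit(X, y, mc)
            table = RankingTable(trait, loc, ids, summ.gebv, k=cfg["top_k"])
            tables.append(table)
            rank_rows.append(table.to_frame())
            if chip_enabled and summ.beta is not None:
                panels.append(chip_mod.make_panel(
                    summ, geno_i, trait, loc, size=cfg["chip"]["size"]))
        pd.concat(rank_rows, ignore_index=True).to_csv(rank_path, sep="\t",
                                                       index=False)
        recs: dict[str, Any] = {"per_trait": {}, "per_locality": {}}
        for trait in traits:
            tt = [t for t in tables if t.trait == trait]
            if len(tt) >= 2:
                recs["per_trait"][trait] = recommendation_domains(
                    tt).to_dict(orient="records")
        for loc in localities:
            lt = [t for t in tables if t.locality == loc]
            if len(lt) >= 2:
                recs["per_locality"][loc] = multi_trait_elites(
                    lt).to_dict(orient="records")
        rec_path.write_text(json.dumps(recs, indent=2, default=str))
        if chip_enabled:
            overlaps = {}
            for trait in traits:
                tp = [p for p in panels if p.trait == trait]
                if len(tp) >= 2:
                    overlaps[f"trait:{trait}"] = chip_mod.overlap_summary(
                        tp, group_by="locality")
            for loc in localities:
                lp = [p for p in panels if p.locality == loc]
                if len(lp) >= 2:
                    overlaps[f"locality:{loc}"] = chip_mod.overlap_summary(
                        lp, group_by="trait")
            overlap_path.write_text(json.dumps(overlaps, indent=2))
            for p in panels:
                pd.DataFrame({
                    "rank": np.arange(1, len(p) + 1),
                    "marker_id": p.markers,
                    "abs_beta": p.scores,
                }).to_csv(outdir / f"chip_{p.trait}_{p.locality}.tsv",
                          sep="\t", index=False)
        stages.done("rank", rank_key)
    artifacts["ranking"] = rank_path
    artifacts["recommendations"] = rec_path

    return {"artifacts": artifacts, "stages": stages.status,
            "summary": best, "outdir": outdir}
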