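"""End-to-end pipeline orchestration over a study directory.

Stages run in the analysis order (fit -> compare -> nulls -> loto -> axis
-> celltype); each stage writes its outputs under the results directory and
records itself in ``manifest.json`` together with the configuration hash
and every seed used.  A completed stage is skipped on rerun with the same
configuration hash unless ``force`` is set; partial results are preserved
on stage failure.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from . import inference as inf
from . import io as rio
from . import model_selection as ms
from .connectome import random_seed_region, rewire_null
from .model import (CompositionAssociation, PathologySpreadModel,
                    VulnerabilityAxisModel)

logger = logging.getLogger(__name__)

STAGES = ("fit", "compare", "nulls", "loto", "axis", "celltype")


def _save_posterior(post: inf.PosteriorSamples, path: Path) -> None:
    priors = {k: (p.kind, p.mu, p.sigma) for k, p in post.priors.items()}
    np.savez_compressed(
        path,
        draws=post.draws, rhat=post.rhat,
        log_likelihood_pointwise=post.log_likelihood_pointwise,
        log_posterior=post.log_posterior,
        names=np.array(post.names), opt_map=post.opt_map,
        model=post.space.model, n_regions=post.space.n_regions,
        seeds=np.array(post.space.seeds),
        bidirectional=post.space.bidirectional,
        priors=json.dumps(priors), settings=json.dumps(post.settings),
    )


def _load_posterior(path: Path) -> inf.PosteriorSamples:
    z = np.load(path, allow_pickle=False)
    priors = {
        k: inf.Prior(kind, mu, sigma)
        for k, (kind, mu, sigma) in json.loads(str(z["priors"])).items()
    }
    space = inf.ParameterSpace(
        str(z["model"]), int(z["n_regions"]), z["seeds"].tolist(), priors,
        bidirectional=bool(z["bidirectional"]),
    )
    return inf.PosteriorSamples(
        draws=z["draws"], names=z["names"].tolist(), rhat=z["rhat"],
        log_likelihood_pointwise=z["log_likelihood_pointwise"],
        log_posterior=z["log_posterior"], space=space, priors=priors,
        opt_map=z["opt_map"], settings=json.loads(str(z["settings"])),
    )


class PipelineRun:
    """Stateful pipeline over one study directory and one configuration."""

    def __init__(self, config: rio.RunConfig, study_dir: str | Path,
                 outdir: str | Path):
        self.config = config
        self.study_dir = Path(study_dir)
        self.outdir = Path(outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.manifest_path = self.outdir / "manifest.json"
        self.manifest = self._load_manifest()
        self.conn = rio.read_connectivity(
            self.study_dir / "connectivity.csv",
            coords_path=(self.study_dir / "coordinates.csv")
            if (self.study_dir / "coordinates.csv").exists() else None,
        )
        self.obs = rio.read_observations(
            self.study_dir / "observations.csv", self.conn.region_ids
        )
        self.seeds = list(config.seeds) or [self.conn.region_ids[0]]
        self._results: dict[str, object] = {}

    # -- manifest ---------------------------------------------------------
    def _load_manifest(self) -> dict:
        if self.manifest_path.exists():
            with open(self.manifest_path) as fh:
                return json.load(fh)
        return {"version": __version__, "stages": {}, "seeds": {}}

    def _write_manifest(self) -> None:
        self.manifest["version"] = __version__
        self.manifest["config_hash"] = self.config.config_hash()
        with open(self.manifest_path, "w") as fh:
            json.dump(self.manifest, fh, indent=1)

    def _done(self, stage: str) -> bool:
        rec = self.manifest["stages"].get(stage)
        return bool(rec and rec.get("config_hash") == self.config.config_hash())

    def _mark(self, stage: str, **extra) -> None:
        self.manifest["stages"][stage] = {
            "config_hash": self.config.config_hash(), **extra
        }
        self.manifest["seeds"][stage] = self.config.rng_seed
        self._write_manifest()

    # -- fitting helpers --------------------------------------------------
    def _fit_model(self, kind: str, obs=None, conn=None, rng_seed=None,
                   seeds=None) -> inf.PosteriorSamples:
        cfg = self.config
        model = PathologySpreadModel(
            obs or self.obs, conn or self.conn, kind=kind,
            transport=cfg.transport, seeds=seeds or self.seeds,
        )
        res = model.fit(
            chains=cfg.chains, warmup=cfg.warmup, samples=cfg.samples,
            target_accept=cfg.target_accept,
            rng_seed=cfg.rng_seed if rng_seed is None else rng_seed,
            rtol=cfg.rtol, atol=cfg.atol,
        )
        return res

    def _main_fit(self):
        """The configured model's fit, from cache when the stage is done."""
        key = f"fit:{self.config.model}"
        if key not in self._results:
            cache = self.outdir / f"posterior_{self.config.model}.npz"
            if self._done("fit") and cache.exists():
                post = _load_posterior(cache)
                model = PathologySpreadModel(
                    self.obs, self.conn, kind=self.config.model,
                    transport=self.config.transport, seeds=self.seeds,
                )
                from .model import PathologySpreadResults
                self._results[key] = PathologySpreadResults(model, post)
            else:
                self._results[key] = self._fit_model(self.config.model)
        return self._results[key]

    # -- stages -----------------------------------------------------------
    def stage_fit(self) -> None:
        res = self._fit_model(self.config.model)
        self._results[f"fit:{self.config.model}"] = res
        _save_posterior(res.posterior, self.outdir / f"posterior_{self.config.model}.npz")
        res.posterior.to_dataframe().to_csv(
            self.outdir / f"draws_{self.config.model}.csv", index=False
        )
        diag = {
            "rhat": dict(zip(res.posterior.names, res.posterior.rhat.tolist())),
            "settings": res.posterior.settings,
            "seed": self.config.rng_seed,
        }
        with open(self.outdir / f"diagnostics_{self.config.model}.json", "w") as fh:
            json.dump(diag, fh, indent=1)
        self._mark("fit")

    def stage_compare(self) -> None:
        metrics = {}
        for kind in ("diff", "diff_r", "diff_rf"):
            key = f"fit:{kind}"
            if key not in self._results:
                self._results[key] = self._fit_model(kind)
            res = self._results[key]
            m = res.metrics
            metrics[kind] = m
            with open(self.outdir / f"metrics_{kind}.json", "w") as fh:
                json.dump({"waic": m.waic, "lppd": m.lppd, "p_waic": m.p_waic,
                           "aic": m.aic, "bic": m.bic, "mse": m.mse,
                           "n_params": m.n_params, "n_obs": m.n_obs}, fh, indent=1)
        ms.delta_table(metrics).to_csv(self.outdir / "model_comparison.csv",
                                       index=False)
        self._mark("compare")

    def stage_nulls(self, n_realizations: int = 3) -> None:
        base = self._main_fit()
        rows = [{"variant": "empirical", "realization": 0,
                 "waic": base.metrics.waic}]
        for r in range(n_realizations):
            seed = self.config.rng_seed + 1000 + r
            conn_null = rewire_null(self.conn, rng_seed=seed)
            post = self._fit_model(self.config.model, conn=conn_null,
                                   rng_seed=seed)
            rows.append({"variant": "rewired", "realization": r,
                         "waic": post.metrics.waic})
            alt = random_seed_region(self.conn, self.seeds, rng_seed=seed)
            alt_labels = [self.conn.region_ids[i] for i in alt]
            post = self._fit_model(self.config.model, rng_seed=seed,
                                   seeds=alt_labels)
            rows.append({"variant": "random_seed", "realization": r,
                         "waic": post.metrics.waic})
        pd.DataFrame(rows).to_csv(self.outdir / "null_models.csv", index=False)
        self._mark("nulls")

    def stage_loto(self) -> None:
        cfg = self.config
        out = {}
        for kind in ("diff_r", "diff_rf"):
            r = ms.leave_one_timepoint_out(
                kind, self._main_fit().model.transport, self.obs,
                seeds=[self.conn.index_of(self.seeds)[0]],
                rng_seed=cfg.rng_seed, chains=cfg.chains, warmup=cfg.warmup,
                samples=cfg.samples,
            )
            out[kind] = {"r2_all": r["r2_all"], "r2_heldout": r["r2_heldout"],
                         "holdout_time": r["holdout_time"]}
        with open(self.outdir / "loto.json", "w") as fh:
            json.dump(out, fh, indent=1)
        self._mark("loto")

    def stage_axis(self) -> None:
        res = self._main_fit()
        expr = rio.read_expression(self.study_dir / "expression.csv")
        vm = VulnerabilityAxisModel.from_results(res, expr)
        vr = vm.fit()
        self._results["axis"] = vr
        vr.coefficients.to_csv(self.outdir / "gene_coefficients.csv")
        ax = vr.axis
        with open(self.outdir / "axis.json", "w") as fh:
            json.dump({
                "c1": ax.c1, "c2": ax.c2,
                "variance_explained_pc1": ax.variance_explained_pc1,
                "regions": vr.regions,
                "eta": ax.eta.tolist(),
            }, fh, indent=1)
        gmt_path = self.study_dir / "genesets.gmt"
        if gmt_path.exists():
            sets = rio.read_gmt(gmt_path)
            cfg = self.config
            enr = vr.gsea(sets, weight_p=cfg.gsea_weight_p,
                          n_perm=cfg.gsea_n_perm, min_size=cfg.gsea_min_size,
                          max_size=cfg.gsea_max_size, rng_seed=cfg.rng_seed)
            enr.to_csv(self.outdir / "gsea.csv")
            from .vulnerability import categorize_pathways, category_enrichment
            cats = categorize_pathways(list(enr.index))
            category_enrichment(cats, enr["fdr"] < 0.05).to_csv(
                self.outdir / "category_enrichment.csv")
        self._mark("axis")

    def stage_celltype(self) -> None:
        if "axis" in self._results:
            vr = self._results["axis"]
        else:
            self.stage_axis()
            vr = self._results["axis"]
        comp = pd.read_csv(self.study_dir / "celltype_fractions.csv",
                           index_col=0)
        base = [_strip(r) for r in vr.regions]
        ca = CompositionAssociation(comp, vr.axis.eta, base)
        car = ca.fit(n_perm=self.config.celltype_n_perm,
                     rng_seed=self.config.rng_seed)
        table = car.per_class.copy()
        table.loc["monoaminergic_score"] = {
            "rho": car.monoaminergic_rho, "p": car.monoaminergic_p,
            "q": np.nan,
        }
        table.to_csv(self.outdir / "celltype_association.csv")
        self._mark("celltype")

    def run(self, stages: Sequence[str] | None = None, force: bool = False) -> Path:
        stages = list(stages or STAGES)
        unknown = set(stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        for stage in STAGES:
            if stage not in stages:
                continue
            if self._done(stage) and not force:
                logger.info("stage %s already complete for this config; skipped",
                            stage)
                continue
            logger.info("running stage %s (seed=%d)", stage, self.config.rng_seed)
            getattr(self, f"stage_{stage}")()
        return self.outdir


def _strip(label: str) -> str:
    for suf in ("_ipsi", "_contra"):
        if label.endswith(suf):
            return label[: -len(suf)]
    return label


def run_pipeline(
    config: rio.RunConfig,
    study_dir: str | Path,
    outdir: str | Path,
    stages: Sequence[str] | None = None,
    force: bool = False,
) -> Path:
    """Run the analysis stages over a study directory; returns the results dir."""
    return PipelineRun(config, study_dir, outdir).run(stages=stages, force=force)
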