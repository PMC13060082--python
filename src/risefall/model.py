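"""High-level modelling API: model objects whose ``fit()`` returns results.

``PathologySpreadModel`` wraps one dynamical model class (DIFF, DIFF-R,
DIFF-RF) on one transport operator for one observation set; ``fit()`` runs
the Bayesian machinery and returns a ``PathologySpreadResults`` carrying
the posterior, diagnostics, MAP parameters, comparison metrics and
prediction helpers.  ``VulnerabilityAxisModel`` and
``CompositionAssociation`` play the same role for the downstream molecular
and cellular analyses.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import celltype as ct
from . import inference as inf
from . import model_selection as ms
from . import vulnerability as vul
from .connectome import Connectome, TransportOperator, make_transport
from .dynamics import ModelParameters, classify_trajectory

__all__ = [
    "PathologySpreadModel",
    "PathologySpreadResults",
    "VulnerabilityAxisModel",
    "VulnerabilityAxisResults",
    "CompositionAssociation",
    "CompositionAssociationResults",
]


class PathologySpreadModel:
    """One spreading-model class bound to data and a transport hypothesis.

    Parameters
    ----------
    obs : ObservationSet
        Replicate-level longitudinal pathology observations.
    connectome : Connectome
        Structural connectivity; the transport operator is built from it.
    kind : {"diff", "diff_r", "diff_rf"}
    transport : {"retrograde", "anterograde", "bidirectional", "euclidean"}
    seeds : region labels (or indices) seeded at t=0
    priors : optional prior overrides (parameter name -> Prior)
    """

    def __init__(
        self,
        obs: inf.ObservationSet,
        connectome: Connectome,
        kind: str = "diff_rf",
        transport: str = "retrograde",
        seeds: Sequence[str] | Sequence[int] = (),
        priors: Mapping[str, inf.Prior] | None = None,
        length_scale: float | None = None,
    ):
        self.obs = obs
        self.connectome = connectome
        self.kind = kind
        self.transport: TransportOperator = make_transport(
            connectome, transport, length_scale=length_scale
        )
        if len(seeds) == 0:
            raise ValueError("at least one seed region is required")
        self.seeds = list(seeds)
        self.priors = dict(priors) if priors is not None else inf.default_priors(
            kind, transport
        )

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, connectome: Connectome, **kwargs
    ) -> "PathologySpreadModel":
        """Build from a long observations table (region,time_months,replicate,value)."""
        obs = inf.ObservationSet.from_dataframe(df, connectome.region_ids)
        return cls(obs, connectome, **kwargs)

    def loglike(self, params: ModelParameters) -> float:
        total, _ = inf.log_likelihood(params, self.transport, self.obs)
        return total

    def fit(
        self,
        chains: int = 4,
        warmup: int = 1000,
        samples: int = 1000,
        target_accept: float = 0.65,
        rng_seed: int = 0,
        **kwargs,
    ) -> "PathologySpreadResults":
        post = inf.fit(
            self.kind, self.transport, self.obs, priors=self.priors,
            seeds=self.seeds, chains=chains, warmup=warmup, samples=samples,
            target_accept=target_accept, rng_seed=rng_seed, **kwargs,
        )
        return PathologySpreadResults(model=self, posterior=post)


@dataclass
class PathologySpreadResults:
    """Posterior, diagnostics and derived quantities of one fitted model."""

    model: PathologySpreadModel
    posterior: inf.PosteriorSamples

    @cached_property
    def map_params(self) -> ModelParameters:
        return inf.map_estimate(self.posterior)

    @cached_property
    def metrics(self) -> ms.FitMetrics:
        return ms.evaluate_fit(self.posterior, self.model.transport, self.model.obs)

    @cached_property
    def updated(self) -> pd.DataFrame:
        """KS posterior-update filter table for every parameter."""
        return inf.updated_flags(self.posterior)

    def predict(self, times: Sequence[float] | None = None) -> np.ndarray:
        """Region x time MAP trajectory on ``times`` (default: the data grid)."""
        ev = inf.LikelihoodEvaluator(
            self.posterior.space, self.model.transport, self.model.obs
        )
        x = self.posterior.space.pack(self.map_params)
        if times is None:
            return ev.forward(x)
        t = np.asarray(times, dtype=float)
        grid = np.concatenate([[0.0], t]) if t[0] > 0 else t
        u = ev.forward(x, grid=grid)
        return u[:, 1:] if t[0] > 0 else u

    def r2_origin(self, log_space: bool = False) -> tuple[float, float]:
        """Pooled predicted-vs-observed through-origin R^2 at the MAP."""
        u = self.predict()
        obs = self.model.obs
        x = u[obs.region_idx, obs.time_idx]
        y = obs.value
        if log_space:
            ok = (x > 0) & (y > 0)
            x, y = np.log10(x[ok]), np.log10(y[ok])
        return ms.r2_origin(x, y)

    def per_timepoint_r2(self, log_space: bool = True) -> pd.DataFrame:
        return ms.per_timepoint_agreement(self.predict(), self.model.obs,
                                          log_space=log_space)

    def trajectory_classes(self, tolerance: float = 1e-3) -> pd.Series:
        """Classify each region's MAP trajectory (flat / rise / rise-and-fall)."""
        u = self.predict()
        return pd.Series(
            [classify_trajectory(u[i], tolerance=tolerance) for i in range(u.shape[0])],
            index=self.model.connectome.region_ids,
        )

    def regional_posterior_means(self) -> pd.DataFrame:
        """Posterior mean beta (and gamma) per region with update flags."""
        post, n = self.posterior, self.model.transport.n_regions
        upd = self.updated.set_index("parameter")
        rows = {}
        for name in ("beta", "gamma"):
            cols = [f"{name}[{i}]" for i in range(n)]
            if all(c in post.names for c in cols):
                rows[name] = [post.marginal(c).mean() for c in cols]
                rows[f"{name}_updated"] = [bool(upd.loc[c, "updated"]) for c in cols]
        return pd.DataFrame(rows, index=self.model.connectome.region_ids)

    def plot_trajectories(self, regions: Sequence[str] | None = None, ax=None):
        """MAP trajectories with the replicate observations overlaid.

        By default the four highest-burden regions are shown.
        """
        import matplotlib.pyplot as plt

        obs = self.model.obs
        u = self.predict()
        if regions is None:
            peak = u.max(axis=1)
            idx = np.argsort(peak)[::-1][:4]
        else:
            idx = self.model.connectome.index_of(regions)
        if ax is None:
            _, ax = plt.subplots()
        dense_t = np.linspace(obs.times[0], obs.times[-1], 80)
        dense = self.predict(dense_t)
        for i in idx:
            label = self.model.connectome.region_ids[i]
            line, = ax.plot(dense_t, dense[i], label=label)
            m = obs.region_idx == i
            ax.plot(obs.times[obs.time_idx[m]], obs.value[m], "o", ms=3,
                    alpha=0.6, color=line.get_color())
        ax.set_xlabel("time (months)")
        ax.set_ylabel("pathology burden")
        ax.legend(fontsize="small")
        return ax

    def summary(self) -> str:
        post = self.posterior
        lines = [
            f"PathologySpreadModel {self.model.kind.upper().replace('_', '-')}"
            f" | transport={self.model.transport.mode}"
            f" | regions={self.model.transport.n_regions}"
            f" | observations={self.model.obs.n_obs}",
            f"chains={post.settings.get('chains')} "
            f"warmup={post.settings.get('warmup')} "
            f"samples={post.settings.get('samples')} "
            f"walkers={post.settings.get('n_walkers')}",
            f"max R-hat = {post.rhat.max():.4f} "
            f"({(post.rhat > 1.05).sum()} parameter(s) above 1.05)",
            f"WAIC = {self.metrics.waic:.2f} (p_waic = {self.metrics.p_waic:.1f}), "
            f"AIC = {self.metrics.aic:.2f}, BIC = {self.metrics.bic:.2f}, "
            f"MSE = {self.metrics.mse:.3e}",
            "",
            f"{'parameter':<14}{'mean':>12}{'sd':>12}{'2.5%':>12}{'97.5%':>12}{'R-hat':>9}",
        ]
        show = [n for n in post.names if "[" not in n]
        for name in show:
            d = post.marginal(name)
            j = post.names.index(name)
            lo, hi = np.percentile(d, [2.5, 97.5])
            lines.append(
                f"{name:<14}{d.mean():>12.4f}{d.std(ddof=1):>12.4f}"
                f"{lo:>12.4f}{hi:>12.4f}{post.rhat[j]:>9.3f}"
            )
        n_regional = sum("[" in n for n in post.names)
        if n_regional:
            lines.append(f"... plus {n_regional} regional parameters "
                         "(see regional_posterior_means())")
        return "\n".join(lines)


class VulnerabilityAxisModel:
    """Gene-expression regressions on (z(beta), z(gamma)) and the PCA axis.

    ``expression`` is regions x genes over hemisphere-resolved labels;
    ``beta``/``gamma`` are per-region posterior means aligned to
    ``region_ids``; ``updated_beta``/``updated_gamma`` the KS filter flags.
    Region selection (beta > 0 and both updated) happens inside ``fit``.
    """

    def __init__(
        self,
        expression: pd.DataFrame,
        beta: Sequence[float],
        gamma: Sequence[float],
        region_ids: Sequence[str],
        updated_beta: Sequence[bool] | None = None,
        updated_gamma: Sequence[bool] | None = None,
    ):
        self.expression = expression
        self.beta = np.asarray(beta, dtype=float)
        self.gamma = np.asarray(gamma, dtype=float)
        self.region_ids = list(region_ids)
        n = len(self.region_ids)
        ones = np.ones(n, dtype=bool)
        self.updated_beta = ones if updated_beta is None else np.asarray(updated_beta, bool)
        self.updated_gamma = ones if updated_gamma is None else np.asarray(updated_gamma, bool)

    @classmethod
    def from_results(
        cls, results: PathologySpreadResults, expression: pd.DataFrame
    ) -> "VulnerabilityAxisModel":
        tab = results.regional_posterior_means()
        return cls(
            expression=expression,
            beta=tab["beta"].values,
            gamma=tab["gamma"].values,
            region_ids=list(tab.index),
            updated_beta=tab["beta_updated"].values,
            updated_gamma=tab["gamma_updated"].values,
        )

    def fit(self) -> "VulnerabilityAxisResults":
        mask = vul.select_regions(self.beta, self.updated_beta, self.updated_gamma)
        kept = [r for r, m in zip(self.region_ids, mask) if m]
        missing = [r for r in kept if r not in self.expression.index]
        if missing:
            raise ValueError(f"expression missing for selected regions: {missing[:5]}")
        zb = vul.standardize(self.beta[mask])
        zg = vul.standardize(self.gamma[mask])
        expr = self.expression.loc[kept]
        coeffs = vul.gene_regressions(expr, zb, zg)
        axis = vul.extract_axis(coeffs, zb, zg, expression=expr, region_ids=kept)
        return VulnerabilityAxisResults(
            model=self, region_mask=mask, regions=kept, z_beta=zb, z_gamma=zg,
            coefficients=coeffs, axis=axis,
        )


@dataclass
class VulnerabilityAxisResults:
    model: VulnerabilityAxisModel
    region_mask: np.ndarray
    regions: list[str]
    z_beta: np.ndarray
    z_gamma: np.ndarray
    coefficients: pd.DataFrame
    axis: vul.VulnerabilityAxis

    def ranked_genes(self) -> pd.Series:
        """Genes ranked (descending) by Pearson correlation with eta."""
        return self.axis.gene_axis_corr.sort_values(ascending=False)

    def gsea(self, gene_sets: Mapping[str, Sequence[str]], **kwargs) -> pd.DataFrame:
        return vul.gsea_preranked(self.axis.gene_axis_corr, gene_sets, **kwargs)

    def compare(self, other: "VulnerabilityAxisResults") -> dict:
        return vul.compare_axes(self.axis, other.axis)

    def plot_coefficients(self, ax=None):
        """Gene cloud in (a, b) coefficient space with the PC1 axis drawn."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        c = (self.axis.gene_axis_corr.values
             if self.axis.gene_axis_corr is not None else None)
        sc = ax.scatter(self.coefficients["a"], self.coefficients["b"], s=6,
                        c=c, cmap="coolwarm")
        if c is not None:
            plt.colorbar(sc, ax=ax, label="corr(expression, eta)")
        span = float(np.abs(self.coefficients[["a", "b"]].values).max())
        ax.plot([-span * self.axis.c1, span * self.axis.c1],
                [-span * self.axis.c2, span * self.axis.c2], "k-", lw=1)
        ax.set_xlabel("coefficient on z(beta)")
        ax.set_ylabel("coefficient on z(gamma)")
        return ax

    def summary(self) -> str:
        ax = self.axis
        return "\n".join([
            f"VulnerabilityAxis over {len(self.regions)} selected regions, "
            f"{self.coefficients.shape[0]} genes",
            f"PC1 loadings (c1, c2) = ({ax.c1:+.3f}, {ax.c2:+.3f}), "
            f"variance explained = {100 * ax.variance_explained_pc1:.1f}%",
            f"eta = {ax.c1:+.3f} z(beta) {ax.c2:+.3f} z(gamma)".replace("+", "+ ").replace("-", "- "),
        ])


class CompositionAssociation:
    """Association between cell-type composition and the regional axis eta.

    ``composition`` is base-region x class fractions (simplex rows);
    ``eta`` is per hemisphere-region with ``base_region`` giving each
    entry's hemisphere-free label (predictors are shared by hemispheres).
    """

    def __init__(
        self,
        composition: pd.DataFrame,
        eta: Sequence[float],
        base_region: Sequence[str],
        pseudocount: float | None = None,
    ):
        self.composition = composition
        self.eta = np.asarray(eta, dtype=float)
        self.base_region = list(base_region)
        self.clr = ct.clr_transform(composition, pseudocount=pseudocount)

    def fit(self, n_perm: int = 10_000, rng_seed: int = 0) -> "CompositionAssociationResults":
        per_class = ct.paired_hemisphere_permutation(
            self.eta, self.base_region, self.clr, n_perm=n_perm, rng_seed=rng_seed
        )
        score = ct.monoaminergic_score(self.clr)
        mono = ct.paired_hemisphere_permutation(
            self.eta, self.base_region, score.to_frame(),
            n_perm=n_perm, rng_seed=rng_seed,
        )
        return CompositionAssociationResults(
            model=self, per_class=per_class,
            monoaminergic_rho=float(mono["rho"].iloc[0]),
            monoaminergic_p=float(mono["p"].iloc[0]),
        )


@dataclass
class CompositionAssociationResults:
    model: CompositionAssociation
    per_class: pd.DataFrame
    monoaminergic_rho: float
    monoaminergic_p: float

    def summary(self) -> str:
        lines = [
            "Cell-type composition vs vulnerability axis (Spearman, "
            "hemisphere-paired permutation)",
            self.per_class.to_string(float_format=lambda v: f"{v:.4f}"),
            f"monoaminergic score: rho = {self.monoaminergic_rho:.3f}, "
            f"p = {self.monoaminergic_p:.4f}",
        ]
        return "\n".join(lines)
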