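"""Molecular vulnerability axis from regional rise/fall parameters.

Given posterior summaries of the regional rise (beta) and fall (gamma)
parameters, each gene's regional expression is regressed on the
standardized parameters,

    expression_g = intercept + a_g z(beta) + b_g z(gamma) + eps,

placing every gene at a point (a_g, b_g) in coefficient space.  PCA across
genes (mean-centred, not variance-scaled: both coordinates are regression
coefficients in the same units) extracts the dominant direction
(c1, c2), normalised and sign-fixed so c2 >= 0, which defines the scalar
regional vulnerability axis

    eta = c1 z(beta) + c2 z(gamma).

Genes are then ranked by the Pearson correlation of their expression with
eta and fed to pre-ranked GSEA (weighted Kolmogorov-Smirnov running sum,
gene-label permutation null), followed by Fisher-exact over-representation
of significant pathways within broad functional categories.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "standardize",
    "select_regions",
    "gene_regressions",
    "VulnerabilityAxis",
    "extract_axis",
    "gsea_preranked",
    "category_enrichment",
    "compare_axes",
    "benjamini_hochberg",
    "DEFAULT_CATEGORY_KEYWORDS",
]

logger = logging.getLogger(__name__)


def standardize(values: Sequence[float]) -> np.ndarray:
    """Z-score a regional vector (mean 0, sample s.d. 1, ddof=1)."""
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("need a 1-D vector of length >= 2")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("constant vector cannot be standardized")
    return (x - x.mean()) / sd


def select_regions(
    post_beta_mean: Sequence[float],
    beta_updated: Sequence[bool],
    gamma_updated: Sequence[bool],
) -> np.ndarray:
    """Regions retained for the biological analyses.

    A region passes iff its posterior-mean rise parameter is positive (fall
    dynamics can only manifest where growth occurs at all) and both of its
    regional parameters were updated from their priors (KS filter).
    Returns the boolean mask; raises if nothing survives.
    """
    beta = np.asarray(post_beta_mean, dtype=float)
    bu = np.asarray(beta_updated, dtype=bool)
    gu = np.asarray(gamma_updated, dtype=bool)
    if not (beta.shape == bu.shape == gu.shape):
        raise ValueError("inputs must have matching shapes")
    mask = (beta > 0) & bu & gu
    if not mask.any():
        raise ValueError(
            "no region passes the beta > 0 + posterior-update filter; "
            "review the KS threshold or the fit"
        )
    return mask


def gene_regressions(
    expression: pd.DataFrame, z_beta: Sequence[float], z_gamma: Sequence[float]
) -> pd.DataFrame:
    """Per-gene OLS of expression on (z(beta), z(gamma)) with intercept.

    ``expression`` is regions x genes over hemisphere-resolved regions
    already restricted to the selected region set.  Returns one row per
    gene with coefficients a (on z(beta)), b (on z(gamma)), intercept and
    the regression R^2.
    """
    zb = np.asarray(z_beta, dtype=float)
    zg = np.asarray(z_gamma, dtype=float)
    Y = np.asarray(expression.values, dtype=float)
    if Y.shape[0] != zb.size or zb.size != zg.size:
        raise ValueError("expression rows must match the parameter vectors")
    if zb.size < 4:
        raise ValueError("need >= 4 regions for a 3-parameter regression")
    r = np.corrcoef(zb, zg)[0, 1]
    if abs(r) >= 0.999:
        raise ValueError(f"z(beta) and z(gamma) are collinear (r={r:.4f})")
    X = np.column_stack([np.ones_like(zb), zb, zg])
    coef, *_ = np.linalg.lstsq(X, Y, rcond=None)
    fitted = X @ coef
    ss_res = ((Y - fitted) ** 2).sum(axis=0)
    ss_tot = ((Y - Y.mean(axis=0)) ** 2).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where(ss_tot > 0, 1.0 - ss_res / ss_tot, np.nan)
    return pd.DataFrame(
        {"a": coef[1], "b": coef[2], "intercept": coef[0], "r2": r2},
        index=expression.columns,
    )


@dataclass
class VulnerabilityAxis:
    """PC1 of gene coefficient space and the induced regional scalar."""

    c1: float
    c2: float
    variance_explained_pc1: float
    eta: np.ndarray | None = None
    region_ids: list[str] = field(default_factory=list)
    gene_axis_corr: pd.Series | None = None

    @property
    def loadings(self) -> np.ndarray:
        return np.array([self.c1, self.c2])


def extract_axis(
    coeffs: pd.DataFrame,
    z_beta: Sequence[float] | None = None,
    z_gamma: Sequence[float] | None = None,
    expression: pd.DataFrame | None = None,
    region_ids: Sequence[str] | None = None,
) -> VulnerabilityAxis:
    """PC1 of the (a, b) gene-coefficient cloud; eta per region.

    PCA is applied to the mean-centred coefficient matrix treating genes as
    observations; loadings are unit-normalised with the sign convention
    c2 >= 0 (positive fall loading).  When the standardized parameters are
    supplied, the per-region axis value eta = c1 z(beta) + c2 z(gamma) is
    computed; when ``expression`` is also given, each gene's Pearson
    correlation with eta is attached.
    """
    A = np.asarray(coeffs[["a", "b"]].values, dtype=float)
    if A.shape[0] < 3:
        raise ValueError("need >= 3 genes for a meaningful PCA")
    C = A - A.mean(axis=0)
    cov = C.T @ C / (C.shape[0] - 1)
    evals, evecs = np.linalg.eigh(cov)  # ascending
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    v = evecs[:, 0]
    if v[1] < 0 or (v[1] == 0 and v[0] < 0):
        v = -v
    total = float(evals.sum())
    var1 = float(evals[0] / total) if total > 0 else np.nan
    axis = VulnerabilityAxis(c1=float(v[0]), c2=float(v[1]),
                             variance_explained_pc1=var1)
    if z_beta is not None and z_gamma is not None:
        zb = np.asarray(z_beta, dtype=float)
        zg = np.asarray(z_gamma, dtype=float)
        axis.eta = axis.c1 * zb + axis.c2 * zg
        axis.region_ids = list(region_ids) if region_ids is not None else []
        if expression is not None:
            E = np.asarray(expression.values, dtype=float)
            eta_c = axis.eta - axis.eta.mean()
            Ec = E - E.mean(axis=0)
            denom = np.sqrt((eta_c**2).sum() * (Ec**2).sum(axis=0))
            with np.errstate(divide="ignore", invalid="ignore"):
                corr = np.where(denom > 0, Ec.T @ eta_c / denom, np.nan)
            axis.gene_axis_corr = pd.Series(corr, index=expression.columns)
    return axis


# --------------------------------------------------------------------------
# pre-ranked GSEA
# --------------------------------------------------------------------------

def _running_sum_es(
    abs_scores_p: np.ndarray, hits: np.ndarray
) -> tuple[float, int]:
    """ES and extremum index of the weighted KS running sum.

    ``abs_scores_p`` are |r|^p along the ranking; ``hits`` a boolean mask.
    Hit steps climb by |r|^p / sum_hits |r|^p, miss steps fall by
    1/(N - N_h).  ES is the extremum of larger magnitude (ties broken
    toward the positive extremum).
    """
    n = abs_scores_p.size
    nh = int(hits.sum())
    nr = abs_scores_p[hits].sum()
    if nh == 0 or nh == n:
        raise ValueError("gene set hits none or all of the ranked genes")
    steps = np.where(hits, abs_scores_p / nr if nr > 0 else 1.0 / nh,
                     -1.0 / (n - nh))
    rs = np.cumsum(steps)
    imax, imin = int(np.argmax(rs)), int(np.argmin(rs))
    if abs(rs[imax]) >= abs(rs[imin]):
        return float(rs[imax]), imax
    return float(rs[imin]), imin


def _permutation_es(
    abs_scores_p: np.ndarray, nh: int, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """Null ES values from random hit-position draws (gene-label permutation)."""
    n = abs_scores_p.size
    miss = -1.0 / (n - nh)
    out = np.empty(n_perm)
    for b in range(n_perm):
        pos = rng.choice(n, size=nh, replace=False)
        hits = np.zeros(n, dtype=bool)
        hits[pos] = True
        nr = abs_scores_p[pos].sum()
        steps = np.where(hits, abs_scores_p / nr if nr > 0 else 1.0 / nh, miss)
        rs = np.cumsum(steps)
        hi, lo = rs.max(), rs.min()
        out[b] = hi if abs(hi) >= abs(lo) else lo
    return out


def gsea_preranked(
    scores: pd.Series,
    gene_sets: Mapping[str, Sequence[str]],
    weight_p: float = 1.0,
    n_perm: int = 1000,
    min_size: int = 10,
    max_size: int = 500,
    rng_seed: int = 0,
) -> pd.DataFrame:
    """Pre-ranked GSEA with gene-label permutation NES.

    ``scores`` maps gene -> ranking score (e.g. correlation with eta); the
    list is sorted descending internally.  Sets are filtered to
    [min_size, max_size] after intersection with the ranked genes.  NES is
    ES divided by the mean |permuted ES| of matching sign; p-values use the
    add-one estimator and are BH-adjusted across sets.
    """
    scores = scores.astype(float)
    if scores.index.has_duplicates:
        raise ValueError("ranked gene list contains duplicate genes")
    if not np.all(np.isfinite(scores.values)):
        raise ValueError("ranking scores must be finite")
    order = np.argsort(-scores.values, kind="stable")
    ranked_genes = scores.index.to_numpy()[order]
    ranked_scores = scores.values[order]
    n = ranked_genes.size
    pos_of = {g: i for i, g in enumerate(ranked_genes)}
    absc = np.abs(ranked_scores) ** weight_p

    kept = {}
    for name, members in gene_sets.items():
        idx = sorted({pos_of[g] for g in members if g in pos_of})
        if min_size <= len(idx) <= max_size:
            if len(idx) == n:
                raise ValueError(f"gene set {name!r} covers every ranked gene")
            kept[name] = np.asarray(idx, dtype=int)
    if not kept:
        raise ValueError("no gene set survives the size filter")

    rng = np.random.default_rng(rng_seed)
    rows = []
    perm_cache: dict[int, np.ndarray] = {}
    for name, idx in kept.items():
        hits = np.zeros(n, dtype=bool)
        hits[idx] = True
        es, extremum = _running_sum_es(absc, hits)
        nh = idx.size
        if nh not in perm_cache:
            perm_cache[nh] = _permutation_es(absc, nh, n_perm, rng)
        null = perm_cache[nh]
        same = null >= 0 if es >= 0 else null < 0
        n_same = int(same.sum())
        denom = np.abs(null[same]).mean() if n_same else np.nan
        nes = es / denom if denom and np.isfinite(denom) and denom > 0 else np.nan
        pval = (1 + int((np.abs(null[same]) >= abs(es)).sum())) / (1 + n_same)
        if es >= 0:
            leading = [g for g in ranked_genes[: extremum + 1] if pos_of[g] in set(idx)]
        else:
            leading = [g for g in ranked_genes[extremum:] if pos_of[g] in set(idx)]
        rows.append({
            "set": name, "es": es, "nes": nes, "p": pval,
            "size": nh, "leading_edge": ",".join(leading),
        })
    out = pd.DataFrame(rows).set_index("set")
    out["fdr"] = benjamini_hochberg(out["p"].values)
    return out


# --------------------------------------------------------------------------
# category over-representation
# --------------------------------------------------------------------------

DEFAULT_CATEGORY_KEYWORDS: dict[str, tuple[str, ...]] = {
    "metabolism": (
        "metabol", "oxidative phosphorylation", "citrate", "tca",
        "glycolysis", "respirat", "pentose", "fatty acid",
    ),
    "protein homeostasis": (
        "proteasome", "ubiquitin", "autophag", "lysosom", "chaperone",
        "protein processing", "protein export", "proteosta", "folding",
    ),
    "synaptic function": (
        "synap", "neurotransmitter", "vesicle", "axon", "neuroactive",
        "long-term potentiation", "long-term depression",
    ),
    "neurodegenerative disease": (
        "parkinson", "alzheimer", "huntington", "prion",
        "neurodegener", "amyotrophic",
    ),
}


def categorize_pathways(
    names: Sequence[str],
    keywords: Mapping[str, Sequence[str]] | None = None,
) -> pd.Series:
    """Keyword-match pathway names into broad functional categories.

    First matching category in the config order wins; unmatched pathways
    fall into ``other``.  The keyword table is an editable configuration.
    """
    kw = keywords or DEFAULT_CATEGORY_KEYWORDS
    out = []
    for name in names:
        low = name.lower()
        for cat, pats in kw.items():
            if any(p in low for p in pats):
                out.append(cat)
                break
        else:
            out.append("other")
    return pd.Series(out, index=list(names), name="category")


def category_enrichment(
    categories: pd.Series, significant: pd.Series
) -> pd.DataFrame:
    """Fisher-exact over-representation of significant pathways per category.

    2x2 table per category (significant vs not x in-category vs not),
    two-sided p, BH q across categories, and log2 odds ratio with the
    Haldane half-count correction when any cell is zero.
    """
    categories = categories.astype(str)
    significant = significant.reindex(categories.index).astype(bool)
    rows = []
    for cat in categories.unique():
        inc = categories == cat
        a = int((significant & inc).sum())
        b = int((significant & ~inc).sum())
        c = int((~significant & inc).sum())
        d = int((~significant & ~inc).sum())
        if a + c == 0:
            logger.warning("category %r has no members; skipped", cat)
            continue
        _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        if min(a, b, c, d) == 0:
            a_, b_, c_, d_ = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        else:
            a_, b_, c_, d_ = a, b, c, d
        log2_or = float(np.log2((a_ * d_) / (b_ * c_)))
        rows.append({"category": cat, "n_in": a + c, "n_sig_in": a,
                     "log2_odds_ratio": log2_or, "p": p})
    out = pd.DataFrame(rows).set_index("category")
    out["q"] = benjamini_hochberg(out["p"].values)
    return out


def compare_axes(
    axis_a: VulnerabilityAxis, axis_b: VulnerabilityAxis
) -> dict:
    """Alignment of two vulnerability axes across datasets.

    Cosine similarity and angle between the PC1 loading vectors, plus
    gene-level statistics over shared genes when both axes carry gene-axis
    correlations: Pearson r, with-intercept OLS slope (B on A), and the
    fraction of genes whose correlation sign agrees.
    """
    va, vb = axis_a.loadings, axis_b.loadings
    cos = float(va @ vb / (np.linalg.norm(va) * np.linalg.norm(vb)))
    angle = float(np.degrees(np.arccos(np.clip(cos, -1.0, 1.0))))
    out = {"cosine": cos, "angle_deg": angle}
    if axis_a.gene_axis_corr is not None and axis_b.gene_axis_corr is not None:
        shared = axis_a.gene_axis_corr.index.intersection(
            axis_b.gene_axis_corr.index)
        if len(shared) == 0:
            raise ValueError("no shared genes between the two axes")
        if len(shared) < 10:
            logger.warning("only %d shared genes; gene-level statistics are "
                           "unstable", len(shared))
        ra = axis_a.gene_axis_corr.loc[shared].values
        rb = axis_b.gene_axis_corr.loc[shared].values
        pearson, pearson_p = stats.pearsonr(ra, rb)
        slope = float(np.polyfit(ra, rb, 1)[0])
        out.update({
            "n_shared_genes": int(len(shared)),
            "gene_corr_pearson_r": float(pearson),
            "gene_corr_pearson_p": float(pearson_p),
            "ols_slope": slope,
            "sign_agreement": float(np.mean(np.sign(ra) == np.sign(rb))),
        })
    return out


def benjamini_hochberg(pvalues: Sequence[float]) -> np.ndarray:
    """Step-up BH adjusted q-values, monotone in the sorted order, capped at 1."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
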