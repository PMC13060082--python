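"""Regional cell-type composition and its association with the axis.

Regional counts per neurotransmitter class are estimated by distributing
each annotated cell cluster's cells across brain structures according to
its reported spatial frequencies, walking contributions up an ontology
(child -> parent map) until a target region is reached.  Fractions are the
class counts normalised by the regional total; being compositional, they
are centred-log-ratio (CLR) transformed before any correlation analysis.

Association with the regional vulnerability axis eta uses Spearman
correlation with a hemisphere-paired permutation null: cell-type predictors
are shared by the two hemispheres of a region, so permutations shuffle
predictor values over *regions* and both hemispheres of a region always
receive the same shuffled value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .vulnerability import benjamini_hochberg

__all__ = [
    "MONOAMINERGIC_CLASSES",
    "CellCluster",
    "estimate_regional_counts",
    "composition_from_counts",
    "clr_transform",
    "spearman",
    "paired_hemisphere_permutation",
    "monoaminergic_score",
]

logger = logging.getLogger(__name__)

MONOAMINERGIC_CLASSES = (
    "dopaminergic", "noradrenergic", "serotonergic", "histaminergic",
)


@dataclass
class CellCluster:
    """One transcriptomic cell cluster: size, class label, spatial frequencies."""

    cluster_id: str
    size: float
    neurotransmitter_class: str
    frequencies: Mapping[str, float]  # structure -> fraction of the cluster

    def __post_init__(self) -> None:
        if self.size < 0:
            raise ValueError(f"cluster {self.cluster_id}: negative size")
        total = sum(self.frequencies.values())
        if total > 1 + 1e-9:
            raise ValueError(
                f"cluster {self.cluster_id}: spatial frequencies sum to {total:.4f} > 1"
            )


def _resolve_structure(
    structure: str, targets: set[str], parent: Mapping[str, str]
) -> str | None:
    """Walk a structure up the ontology until a target region is hit."""
    seen = set()
    s = structure
    while s not in targets:
        if s in seen:
            raise ValueError(f"ontology cycle detected at {s!r}")
        seen.add(s)
        if s not in parent:
            return None  # reached a root outside the target set
        s = parent[s]
    return s


def estimate_regional_counts(
    clusters: Sequence[CellCluster],
    ontology: Mapping[str, str],
    target_regions: Sequence[str],
) -> pd.DataFrame:
    """Estimated cell counts per target region and neurotransmitter class.

    Each cluster's cells are split proportionally to its spatial
    frequencies; contributions at structures outside the target set are
    propagated up the child -> parent ontology, and dropped with a warning
    if a root is reached without hitting a target.  Counts are aggregated
    by class; total cells are conserved minus the warned drops.
    """
    targets = set(target_regions)
    classes = sorted({c.neurotransmitter_class for c in clusters})
    counts = pd.DataFrame(0.0, index=list(target_regions), columns=classes)
    dropped = 0.0
    for cl in clusters:
        for structure, freq in cl.frequencies.items():
            cells = cl.size * freq
            if cells == 0:
                continue
            resolved = _resolve_structure(structure, targets, ontology)
            if resolved is None:
                dropped += cells
                logger.warning(
                    "cluster %s: %.1f cells at %r have no target ancestor; dropped",
                    cl.cluster_id, cells, structure,
                )
                continue
            counts.loc[resolved, cl.neurotransmitter_class] += cells
    if dropped:
        logger.warning("total dropped cells: %.1f", dropped)
    return counts


def composition_from_counts(counts: pd.DataFrame) -> pd.DataFrame:
    """Row-normalise counts to per-region fractions (rows on the simplex)."""
    totals = counts.sum(axis=1)
    zero = totals == 0
    if zero.any():
        raise ValueError(
            f"regions with zero estimated cells: {list(counts.index[zero])[:5]}"
        )
    return counts.div(totals, axis=0)


def clr_transform(
    fractions: pd.DataFrame | np.ndarray, pseudocount: float | None = None
) -> pd.DataFrame | np.ndarray:
    """Centred log-ratio transform, row-wise: log(x_i / geometric_mean(x)).

    Zeros are handled by multiplicative replacement: add a pseudocount
    (default: half the smallest nonzero fraction in the matrix) and
    renormalise rows.  Every output row sums to zero.
    """
    is_df = isinstance(fractions, pd.DataFrame)
    X = np.asarray(fractions, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
        squeeze = True
    else:
        squeeze = False
    if np.any(X < 0):
        raise ValueError("fractions must be nonnegative")
    if np.any(X.sum(axis=1) == 0):
        raise ValueError("all-zero composition row")
    if np.any(X == 0):
        if pseudocount is None:
            pseudocount = X[X > 0].min() / 2.0
        if pseudocount <= 0:
            raise ValueError("pseudocount must be positive")
        X = X + pseudocount
    X = X / X.sum(axis=1, keepdims=True)
    logX = np.log(X)
    out = logX - logX.mean(axis=1, keepdims=True)
    if squeeze:
        out = out[0]
    if is_df:
        return pd.DataFrame(out, index=fractions.index, columns=fractions.columns)
    return out


def spearman(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation (mid-ranks for ties)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length vectors of length >= 3")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        raise ValueError("Spearman correlation undefined for constant input")
    return float(stats.spearmanr(x, y).statistic)


def paired_hemisphere_permutation(
    eta: Sequence[float],
    base_region: Sequence[str],
    predictors: pd.DataFrame,
    n_perm: int = 10_000,
    rng_seed: int = 0,
) -> pd.DataFrame:
    """Spearman association of eta with region-level predictors, paired null.

    ``eta`` is per hemisphere-region (one value per row), ``base_region``
    gives each row's hemisphere-free region label, and ``predictors`` is
    indexed by base region (one shared value per region, e.g. CLR cell-type
    components).  The permutation null shuffles predictor values across
    regions while both hemispheres of a region always share one value;
    empirical two-sided p-values use the add-one estimator
    p = (1 + #{|rho_perm| >= |rho_obs|}) / (1 + n_perm), BH-adjusted across
    predictors.
    """
    eta = np.asarray(eta, dtype=float)
    base = np.asarray(base_region, dtype=object)
    if eta.size != base.size:
        raise ValueError("eta and base_region must align")
    regions = pd.unique(base)
    missing = [r for r in regions if r not in predictors.index]
    if missing:
        raise ValueError(f"predictors missing for regions: {missing[:5]}")
    region_pos = {r: i for i, r in enumerate(regions)}
    expand = np.array([region_pos[r] for r in base])  # row -> region slot

    P = predictors.loc[regions].to_numpy(dtype=float)  # regions x k
    rng = np.random.default_rng(rng_seed)
    rows = []
    rho_obs = np.array([spearman(eta, P[expand, j]) for j in range(P.shape[1])])
    exceed = np.zeros(P.shape[1], dtype=int)
    for _ in range(n_perm):
        perm = rng.permutation(len(regions))
        Pp = P[perm][expand]  # both hemispheres get the same shuffled value
        for j in range(P.shape[1]):
            if abs(spearman(eta, Pp[:, j])) >= abs(rho_obs[j]):
                exceed[j] += 1
    pvals = (1 + exceed) / (1 + n_perm)
    for j, col in enumerate(predictors.columns):
        rows.append({"predictor": col, "rho": float(rho_obs[j]),
                     "p": float(pvals[j])})
    out = pd.DataFrame(rows).set_index("predictor")
    out["q"] = benjamini_hochberg(out["p"].values)
    return out


def monoaminergic_score(
    clr_components: pd.DataFrame,
    classes: Sequence[str] = MONOAMINERGIC_CLASSES,
) -> pd.Series:
    """Per-region mean of the CLR components of the monoaminergic classes."""
    missing = [c for c in classes if c not in clr_components.columns]
    if missing:
        raise ValueError(f"missing neurotransmitter classes: {missing}")
    return clr_components[list(classes)].mean(axis=1).rename("monoaminergic_score")
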