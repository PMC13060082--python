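"""Synthetic studies with the statistical structure the pipeline assumes.

The generator produces, from one master seed, a complete mock seeding
experiment: a mirrored two-hemisphere directed connectome, rise-and-fall
pathology trajectories observed with Gaussian replicate noise on the
canonical 0.1-9 month grid, a region x gene expression matrix whose
gene coefficients lie along a planted axis in (z(beta), z(gamma)) space,
Dirichlet cell-type compositions whose monoaminergic share is tilted by the
planted axis, and a gene-set collection with planted enriched sets.

Default truth scales are chosen so that rise-and-fall happens inside the
sampling window (rise timescale 1/(alpha*beta) of order a month) with
observation noise well below peak burden - the regime in which the real
experiments are interpretable at all.  Every component is reproducible
bit-for-bit from the master seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .celltype import MONOAMINERGIC_CLASSES
from .connectome import Connectome, make_transport
from .dynamics import ModelParameters, simulate
from .inference import ObservationSet

__all__ = [
    "DEFAULT_TIMEPOINTS",
    "DEFAULT_CLASSES",
    "gen_connectome",
    "gen_pathology",
    "gen_expression",
    "duplicate_hemispheres",
    "gen_celltypes",
    "gen_genesets",
    "SyntheticStudy",
    "make_study",
]

DEFAULT_TIMEPOINTS = (0.1, 0.2, 0.3, 0.5, 1.0, 3.0, 6.0, 9.0)

DEFAULT_CLASSES = (
    "glutamatergic", "gabaergic", "dopaminergic", "noradrenergic",
    "serotonergic", "histaminergic", "other",
)


def gen_connectome(
    n_regions_per_hemisphere: int = 20,
    density: float = 0.25,
    weight_scale: float = 1.0,
    rng_seed: int = 0,
) -> Connectome:
    """Mirrored two-hemisphere directed connectome with log-normal weights.

    Both hemispheres share one intra-hemispheric wiring diagram; sparse
    commissural edges couple them.  Strong connectivity is guaranteed by
    adding bridging edges where needed (pathology must be able to spread
    from any seed under any transport direction), and 3-D centroids
    (mirrored in x) are attached so the Euclidean transport mode is
    exercisable.
    """
    n = int(n_regions_per_hemisphere)
    if n < 5:
        raise ValueError("need at least 5 regions per hemisphere")
    if not 0 < density <= 1:
        raise ValueError("density must be in (0, 1]")
    rng = np.random.default_rng(rng_seed)

    def block() -> np.ndarray:
        A = (rng.random((n, n)) < density).astype(float)
        np.fill_diagonal(A, 0.0)
        Wb = A * rng.lognormal(mean=np.log(weight_scale), sigma=0.75, size=(n, n))
        return Wb

    intra = block()
    W = np.zeros((2 * n, 2 * n))
    W[:n, :n] = intra
    W[n:, n:] = intra
    # sparser, weaker commissural projections, mirrored
    commissural = (rng.random((n, n)) < density / 2).astype(float)
    cw = commissural * rng.lognormal(np.log(weight_scale) - 0.5, 0.75, (n, n))
    W[:n, n:] = cw
    W[n:, :n] = cw

    # guarantee strong connectivity by bridging components: pathology must
    # be able to reach (and be reached from) every region regardless of the
    # transport direction hypothesis, as in the real connectome
    G = nx.from_numpy_array(W, create_using=nx.DiGraph)
    while not nx.is_strongly_connected(G):
        comps = list(nx.strongly_connected_components(G))
        a = int(rng.choice(sorted(comps[0])))
        b = int(rng.choice(sorted(comps[1])))
        for (i, j) in ((b, a), (a, b)):
            if W[i, j] == 0:
                w = rng.lognormal(np.log(weight_scale), 0.5)
                W[i, j] = w
                # mirrored counterpart keeps the hemispheres exchangeable
                W[(i + n) % (2 * n), (j + n) % (2 * n)] = w
        G = nx.from_numpy_array(W, create_using=nx.DiGraph)

    # normalise to unit mean out-strength so the transport rate rho is the
    # sole overall diffusion timescale (as with normalised tracer data)
    out_strength = W.sum(axis=0)
    W *= weight_scale / out_strength[out_strength > 0].mean()

    labels = [f"R{i:03d}_ipsi" for i in range(n)] + [
        f"R{i:03d}_contra" for i in range(n)
    ]
    xyz = rng.uniform(0.0, 10.0, size=(n, 3))
    xyz[:, 0] = rng.uniform(1.0, 10.0, size=n)  # keep off the midline
    mirrored = xyz.copy()
    mirrored[:, 0] *= -1.0
    coords = np.vstack([xyz, mirrored])
    return Connectome(region_ids=labels, W=W, coords=coords)


def gen_pathology(
    conn: Connectome,
    model: str = "diff_rf",
    timepoints: Sequence[float] = DEFAULT_TIMEPOINTS,
    n_replicates: int = 3,
    sigma: float = 0.01,
    rng_seed: int = 0,
    seeds: Sequence[str] | None = None,
    grow_fraction: float = 0.6,
    fall_fraction: float = 0.6,
    rho_range: tuple[float, float] = (0.3, 0.7),
    alpha_range: tuple[float, float] = (1.8, 2.4),
    beta_grow_range: tuple[float, float] = (0.4, 1.1),
    gamma_range: tuple[float, float] = (0.1, 0.9),
    u0: float = 0.5,
    transport_mode: str = "retrograde",
    clip_negative: bool = False,
) -> tuple[ObservationSet, ModelParameters]:
    """Simulate a seeding experiment and observe it with replicate noise.

    True parameters are drawn from the given ranges: a ``grow_fraction`` of
    regions receives a positive rise parameter, of which a
    ``fall_fraction`` receives a positive fall parameter (the rest fall at
    essentially zero rate); hemisphere mirror pairs share their regional
    parameters, mimicking bilateral symmetry of regional identity.
    Observations are y = u(t) + N(0, sigma^2), kept negative unless
    ``clip_negative``.
    """
    rng = np.random.default_rng(rng_seed)
    n = conn.n_regions
    if seeds is None:
        seeds = [conn.region_ids[0]]
    seed_idx = conn.index_of(seeds)

    pairs = conn.hemisphere_pairs()
    rho = float(rng.uniform(*rho_range))
    alpha = float(rng.uniform(*alpha_range))

    beta = np.empty(n)
    gamma = np.empty(n)
    # assign per base-region so hemisphere mirror pairs share their values;
    # "no-fall" regions still get a tiny positive rate (the fall prior has
    # support (0, inf), so exact zeros would lie outside the model family)
    bases = list(pairs) if pairs else [str(i) for i in range(n)]
    for base in bases:
        idxs = pairs[base] if pairs else (int(base),)
        b = rng.uniform(0.0, 0.05)
        g = rng.uniform(0.005, 0.03)
        if rng.random() < grow_fraction:
            b = rng.uniform(*beta_grow_range)
            if rng.random() < fall_fraction:
                g = rng.uniform(*gamma_range)
        for i in idxs:
            beta[i] = b
            gamma[i] = g
    # the seed region always grows (otherwise nothing happens)
    for i in seed_idx:
        if beta[i] < beta_grow_range[0]:
            beta[i] = rng.uniform(*beta_grow_range)

    if model == "diff":
        params = ModelParameters(model="diff", rho=rho, u0=u0 * n, sigma=sigma,
                                 seeds=list(seed_idx))
    elif model == "diff_r":
        params = ModelParameters(model="diff_r", rho=rho, alpha=alpha, beta=beta,
                                 u0=u0, sigma=sigma, seeds=list(seed_idx))
    else:
        params = ModelParameters(model="diff_rf", rho=rho, alpha=alpha, beta=beta,
                                 gamma=gamma, u0=u0, sigma=sigma,
                                 seeds=list(seed_idx))
    transport = make_transport(conn, transport_mode)
    traj = simulate(params, transport, timepoints)

    records = []
    for t_i, t in enumerate(traj.times):
        for r_i in range(n):
            for rep in range(n_replicates):
                y = traj.u[r_i, t_i] + rng.normal(0.0, sigma)
                if clip_negative:
                    y = max(y, 0.0)
                records.append((conn.region_ids[r_i], float(t), rep, y))
    df = pd.DataFrame(records, columns=["region", "time_months", "replicate", "value"])
    obs = ObservationSet.from_dataframe(df, conn.region_ids)
    return obs, params


def gen_expression(
    z_beta: Sequence[float],
    z_gamma: Sequence[float],
    region_ids: Sequence[str],
    n_genes: int = 2000,
    axis_direction: Sequence[float] = (-0.37, 0.93),
    anisotropy: float = 10.0,
    coeff_scale: float = 1.0,
    noise_sd: float = 1.0,
    rng_seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Expression built as linear functions of z(beta), z(gamma) plus noise.

    Per-gene coefficient pairs (a_g, b_g) are drawn from a 2-D Gaussian
    elongated along ``axis_direction`` (unit-normalised internally) by the
    ``anisotropy`` factor, so the planted PC1 of the coefficient cloud is
    that direction.  Returns the single-hemisphere region x gene matrix and
    the planted coefficient table.
    """
    zb = np.asarray(z_beta, dtype=float)
    zg = np.asarray(z_gamma, dtype=float)
    if zb.shape != zg.shape or zb.size != len(region_ids):
        raise ValueError("z vectors and region_ids must align")
    v = np.asarray(axis_direction, dtype=float)
    v = v / np.linalg.norm(v)
    if v[1] < 0:
        v = -v
    if anisotropy < 1:
        raise ValueError("anisotropy must be >= 1")
    rng = np.random.default_rng(rng_seed)
    w = np.array([-v[1], v[0]])  # orthogonal direction
    s_major = rng.normal(0.0, coeff_scale, size=n_genes)
    s_minor = rng.normal(0.0, coeff_scale / anisotropy, size=n_genes)
    ab = np.outer(s_major, v) + np.outer(s_minor, w)  # genes x 2
    genes = [f"G{i:04d}" for i in range(n_genes)]
    intercepts = rng.normal(5.0, 1.0, size=n_genes)
    E = (
        intercepts[None, :]
        + np.outer(zb, ab[:, 0])
        + np.outer(zg, ab[:, 1])
        + rng.normal(0.0, noise_sd, size=(zb.size, n_genes))
    )
    expr = pd.DataFrame(E, index=list(region_ids), columns=genes)
    planted = pd.DataFrame({"a": ab[:, 0], "b": ab[:, 1]}, index=genes)
    planted.attrs["axis_direction"] = v
    return expr, planted


def duplicate_hemispheres(expr: pd.DataFrame) -> pd.DataFrame:
    """Mirror a single-hemisphere expression table onto both hemispheres.

    Rows indexed by base region labels come back duplicated with ``_ipsi``
    and ``_contra`` suffixes and identical per-gene values within a pair.
    """
    rows, index = [], []
    for base, row in expr.iterrows():
        for suf in ("_ipsi", "_contra"):
            rows.append(row.values)
            index.append(f"{base}{suf}")
    return pd.DataFrame(rows, index=index, columns=expr.columns)


def gen_celltypes(
    eta: Sequence[float],
    region_ids: Sequence[str],
    classes: Sequence[str] = DEFAULT_CLASSES,
    coupling_strength: float = 3.0,
    concentration: float = 40.0,
    rng_seed: int = 0,
) -> pd.DataFrame:
    """Dirichlet compositions whose monoaminergic share is tilted by eta.

    Base concentrations put most mass in the glutamatergic/GABAergic/other
    classes; the concentration of each monoaminergic class in region i is
    scaled by exp(coupling_strength * eta_i).  ``coupling_strength = 0``
    gives the exchangeable null.
    """
    eta = np.asarray(eta, dtype=float)
    if eta.size != len(region_ids):
        raise ValueError("eta and region_ids must align")
    if coupling_strength < 0:
        raise ValueError("coupling_strength must be >= 0")
    rng = np.random.default_rng(rng_seed)
    base = np.array(
        [0.45 if c in ("glutamatergic", "gabaergic") else
         0.06 if c in MONOAMINERGIC_CLASSES else 0.12 for c in classes]
    )
    base = base / base.sum() * concentration
    mono = np.array([c in MONOAMINERGIC_CLASSES for c in classes])
    eta_c = eta - eta.mean()
    scale = eta_c / eta_c.std(ddof=1) if eta_c.std(ddof=1) > 0 else eta_c
    rows = np.empty((eta.size, len(classes)))
    for i in range(eta.size):
        conc = base.copy()
        conc[mono] *= np.exp(coupling_strength * scale[i] * 0.35)
        rows[i] = rng.dirichlet(conc)
    return pd.DataFrame(rows, index=list(region_ids), columns=list(classes))


def gen_genesets(
    genes: Sequence[str],
    axis_corr: pd.Series | None = None,
    n_sets: int = 100,
    size_range: tuple[int, int] = (10, 100),
    n_planted: int = 10,
    planted_bias: float = 4.0,
    rng_seed: int = 0,
) -> tuple[dict[str, list[str]], list[str]]:
    """Random gene sets plus planted sets biased toward axis-aligned genes.

    Planted sets sample genes with probability proportional to
    ``|axis correlation|^planted_bias`` (computed from ``axis_corr``),
    concentrating them in the tails of the ranking; random sets sample
    uniformly.  Returns the GMT-style mapping and the planted set names.
    """
    genes = list(genes)
    lo, hi = size_range
    if lo < 2 or hi > len(genes):
        raise ValueError("size range must lie within [2, n_genes]")
    rng = np.random.default_rng(rng_seed)
    sets: dict[str, list[str]] = {}
    planted_names = []
    if n_planted and axis_corr is None:
        raise ValueError("planted sets require axis correlations")
    for k in range(n_planted):
        size = int(rng.integers(lo, hi + 1))
        w = np.abs(axis_corr.reindex(genes).fillna(0.0).values) ** planted_bias
        # plant in one tail so the running-sum extremum is coherent
        sign = 1 if k % 2 == 0 else -1
        w = w * (np.sign(axis_corr.reindex(genes).values) == sign)
        if w.sum() == 0 or int((w > 0).sum()) < size:
            w = np.abs(axis_corr.reindex(genes).fillna(0.0).values) ** planted_bias
        size = min(size, int((w > 0).sum()))
        p = w / w.sum()
        members = rng.choice(genes, size=size, replace=False, p=p)
        name = f"PLANTED_SET_{k:02d}"
        sets[name] = sorted(members.tolist())
        planted_names.append(name)
    for k in range(n_sets - n_planted):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(genes, size=size, replace=False)
        sets[f"RANDOM_SET_{k:03d}"] = sorted(members.tolist())
    return sets, planted_names


@dataclass
class SyntheticStudy:
    """A complete mock seeding study plus its planted ground truth."""

    connectome: Connectome
    observations: ObservationSet
    true_params: ModelParameters
    expression: pd.DataFrame  # hemisphere-duplicated, regions x genes
    celltypes: pd.DataFrame  # base regions x classes, rows on the simplex
    genesets: dict[str, list[str]]
    ground_truth: dict = field(default_factory=dict)
    rng_seed: int = 0


def make_study(
    rng_seed: int = 0,
    n_regions_per_hemisphere: int = 20,
    n_genes: int = 2000,
    n_sets: int = 100,
    n_replicates: int = 3,
    sigma: float = 0.01,
    density: float = 0.25,
    axis_direction: Sequence[float] = (-0.37, 0.93),
    anisotropy: float = 10.0,
    expression_noise_sd: float = 1.0,
    celltype_coupling: float = 3.0,
    seeds: Sequence[str] | None = None,
    timepoints: Sequence[float] = DEFAULT_TIMEPOINTS,
) -> SyntheticStudy:
    """Generate every component of a study from one master seed.

    Sub-seeds for each component are derived deterministically from the
    master seed.  The planted axis eta is computed from the *true*
    standardized regional parameters over grown regions of one hemisphere;
    expression is generated per base region and duplicated across
    hemispheres, and cell-type compositions are coupled to the planted eta.
    """
    ss = np.random.SeedSequence(rng_seed)
    sub = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(5)]
    conn = gen_connectome(n_regions_per_hemisphere, density=density,
                          rng_seed=sub[0])
    obs, params = gen_pathology(
        conn, model="diff_rf", timepoints=timepoints,
        n_replicates=n_replicates, sigma=sigma, rng_seed=sub[1], seeds=seeds,
    )

    # planted axis over one hemisphere's base regions
    pairs = conn.hemisphere_pairs()
    bases = list(pairs)
    ipsi_idx = np.array([pairs[b][0] for b in bases])
    beta_b = params.beta[ipsi_idx]
    gamma_b = params.gamma[ipsi_idx]
    zb = (beta_b - beta_b.mean()) / beta_b.std(ddof=1)
    zg = (gamma_b - gamma_b.mean()) / gamma_b.std(ddof=1)
    v = np.asarray(axis_direction, dtype=float)
    v = v / np.linalg.norm(v)
    if v[1] < 0:
        v = -v
    eta = v[0] * zb + v[1] * zg

    expr_base, planted_coeffs = gen_expression(
        zb, zg, bases, n_genes=n_genes, axis_direction=v,
        anisotropy=anisotropy, noise_sd=expression_noise_sd, rng_seed=sub[2],
    )
    expr = duplicate_hemispheres(expr_base)

    # gene-axis correlation implied by the planted coefficients
    E = expr_base.values
    eta_c = eta - eta.mean()
    Ec = E - E.mean(axis=0)
    denom = np.sqrt((eta_c**2).sum() * (Ec**2).sum(axis=0))
    corr = pd.Series(
        np.where(denom > 0, Ec.T @ eta_c / denom, 0.0), index=expr_base.columns
    )
    hi = min(100, max(10, n_genes // 3))
    genesets, planted_sets = gen_genesets(
        list(expr_base.columns), axis_corr=corr, n_sets=n_sets,
        size_range=(min(10, hi), hi), rng_seed=sub[3],
    )
    celltypes = gen_celltypes(eta, bases, coupling_strength=celltype_coupling,
                              rng_seed=sub[4])
    return SyntheticStudy(
        connectome=conn,
        observations=obs,
        true_params=params,
        expression=expr,
        celltypes=celltypes,
        genesets=genesets,
        ground_truth={
            "axis_direction": v,
            "eta": eta,
            "base_regions": bases,
            "planted_sets": planted_sets,
            "planted_coefficients": planted_coeffs,
            "gene_axis_corr": corr,
            "celltype_coupling": celltype_coupling,
            "sub_seeds": sub,
        },
        rng_seed=rng_seed,
    )
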