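"""Readers, writers, and run configuration.

Canonical plain-text interchange formats:

- connectivity: square CSV, header row + first column = region labels,
  hemisphere encoded in the label suffix (``_ipsi``/``_contra``);
  optional coordinates CSV with columns region,x,y,z
- observations: long CSV with columns region,time_months,replicate,value
- expression: CSV, regions x genes with header
- cell clusters: CSV cluster_id,size,class + long CSV
  cluster_id,structure,frequency + ontology JSON child -> parent map
- gene sets: GMT (tab-separated: name, description, member genes)
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .celltype import CellCluster
from .connectome import Connectome
from .inference import ObservationSet

__all__ = [
    "read_connectivity", "write_connectivity",
    "read_observations", "write_observations",
    "read_expression", "write_expression",
    "read_clusters",
    "read_gmt", "write_gmt",
    "RunConfig", "load_config", "write_study",
]

logger = logging.getLogger(__name__)


def read_connectivity(
    path: str | Path, coords_path: str | Path | None = None
) -> Connectome:
    """Load a square weighted connectivity CSV (labels in header + first column)."""
    df = pd.read_csv(path, index_col=0)
    if df.shape[0] != df.shape[1]:
        raise ValueError(f"{path}: connectivity matrix is {df.shape}, not square")
    if list(df.index) != list(df.columns):
        raise ValueError(f"{path}: row and column labels disagree")
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].tolist()
        raise ValueError(f"{path}: duplicate region labels {dups[:5]}")
    try:
        W = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"{path}: non-numeric connectivity cell ({exc})") from exc
    coords = None
    if coords_path is not None:
        cdf = pd.read_csv(coords_path)
        required = {"region", "x", "y", "z"}
        if not required <= set(cdf.columns):
            raise ValueError(f"{coords_path}: needs columns {sorted(required)}")
        cdf = cdf.set_index("region")
        missing = [r for r in df.index if r not in cdf.index]
        if missing:
            raise ValueError(f"{coords_path}: missing coordinates for {missing[:5]}")
        coords = cdf.loc[df.index, ["x", "y", "z"]].to_numpy(dtype=float)
    return Connectome(region_ids=list(df.index), W=W, coords=coords)


def write_connectivity(conn: Connectome, path: str | Path,
                       coords_path: str | Path | None = None) -> None:
    pd.DataFrame(conn.W, index=conn.region_ids, columns=conn.region_ids).to_csv(path)
    if coords_path is not None and conn.coords is not None:
        pd.DataFrame(conn.coords, columns=["x", "y", "z"]).assign(
            region=conn.region_ids
        )[["region", "x", "y", "z"]].to_csv(coords_path, index=False)


def read_observations(path: str | Path, region_ids: Sequence[str]) -> ObservationSet:
    df = pd.read_csv(path)
    return ObservationSet.from_dataframe(df, region_ids)


def write_observations(obs: ObservationSet, path: str | Path) -> None:
    obs.to_dataframe().to_csv(path, index=False)


def read_expression(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, index_col=0)
    if df.index.has_duplicates:
        raise ValueError(f"{path}: duplicate region labels")
    if not np.all(np.isfinite(df.to_numpy(dtype=float))):
        raise ValueError(f"{path}: non-finite expression values")
    return df


def write_expression(expr: pd.DataFrame, path: str | Path) -> None:
    expr.to_csv(path)


def read_clusters(
    clusters_path: str | Path,
    frequencies_path: str | Path,
    ontology_path: str | Path | None = None,
) -> tuple[list[CellCluster], dict[str, str]]:
    """Load cluster annotations, spatial frequencies, and the ontology map."""
    cdf = pd.read_csv(clusters_path)
    required = {"cluster_id", "size", "class"}
    if not required <= set(cdf.columns):
        raise ValueError(f"{clusters_path}: needs columns {sorted(required)}")
    fdf = pd.read_csv(frequencies_path)
    required = {"cluster_id", "structure", "frequency"}
    if not required <= set(fdf.columns):
        raise ValueError(f"{frequencies_path}: needs columns {sorted(required)}")
    freq_by_cluster: dict[str, dict[str, float]] = {}
    for _, row in fdf.iterrows():
        freq_by_cluster.setdefault(str(row["cluster_id"]), {})[
            str(row["structure"])
        ] = float(row["frequency"])
    clusters = [
        CellCluster(
            cluster_id=str(row["cluster_id"]),
            size=float(row["size"]),
            neurotransmitter_class=str(row["class"]),
            frequencies=freq_by_cluster.get(str(row["cluster_id"]), {}),
        )
        for _, row in cdf.iterrows()
    ]
    ontology: dict[str, str] = {}
    if ontology_path is not None:
        with open(ontology_path) as fh:
            ontology = {str(k): str(v) for k, v in json.load(fh).items()}
    return clusters, ontology


def read_gmt(path: str | Path, min_size: int = 1) -> dict[str, list[str]]:
    """Parse a GMT file; sets smaller than ``min_size`` are filtered with a warning."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line needs name, description and "
                    f">= 1 gene (got {len(parts)} fields)"
                )
            name, _desc, *genes = parts
            genes = [g for g in genes if g]
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate set name {name!r}")
            if len(genes) < min_size:
                logger.warning("%s:%d: set %r has %d genes (< %d); filtered",
                               path, lineno, name, len(genes), min_size)
                continue
            sets[name] = genes
    return sets


def write_gmt(sets: Mapping[str, Sequence[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, "na", *genes]) + "\n")


# --------------------------------------------------------------------------
# run configuration
# --------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Pipeline settings; defaults mirror the study's canonical values.

    MCMC 4 chains / 1000 warmup / 1000 samples / target accept 0.65;
    posterior-update KS alpha 0.001; GSEA 1000 permutations, set sizes
    10-500; cell-type permutation test 10,000 permutations.
    """

    model: str = "diff_rf"
    transport: str = "retrograde"
    seeds: list[str] = field(default_factory=list)
    chains: int = 4
    warmup: int = 1000
    samples: int = 1000
    target_accept: float = 0.65
    rng_seed: int = 0
    rtol: float = 1e-6
    atol: float = 1e-9
    ks_alpha: float = 0.001
    gsea_weight_p: float = 1.0
    gsea_n_perm: int = 1000
    gsea_min_size: int = 10
    gsea_max_size: int = 500
    celltype_n_perm: int = 10000
    prior_overrides: dict = field(default_factory=dict)
    paths: dict = field(default_factory=dict)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = set(RunConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
    return RunConfig(**raw)


def write_study(study, outdir: str | Path) -> None:
    """Write every component of a synthetic study as plain-text files."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_connectivity(study.connectome, out / "connectivity.csv",
                       coords_path=out / "coordinates.csv")
    write_observations(study.observations, out / "observations.csv")
    write_expression(study.expression, out / "expression.csv")
    study.celltypes.rename_axis("region").to_csv(out / "celltype_fractions.csv")
    write_gmt(study.genesets, out / "genesets.gmt")
    gt = study.ground_truth
    serializable = {
        "rng_seed": study.rng_seed,
        "axis_direction": np.asarray(gt["axis_direction"]).tolist(),
        "eta": np.asarray(gt["eta"]).tolist(),
        "base_regions": list(gt["base_regions"]),
        "planted_sets": list(gt["planted_sets"]),
        "celltype_coupling": gt["celltype_coupling"],
        "true_params": {
            "model": study.true_params.model,
            "rho": study.true_params.rho,
            "alpha": study.true_params.alpha,
            "u0": study.true_params.u0,
            "sigma": study.true_params.sigma,
            "seeds": [study.connectome.region_ids[i] for i in study.true_params.seeds],
            "beta": study.true_params.beta.tolist(),
            "gamma": study.true_params.gamma.tolist(),
        },
    }
    with open(out / "ground_truth.json", "w") as fh:
        json.dump(serializable, fh, indent=1)
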