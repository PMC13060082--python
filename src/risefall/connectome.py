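"""Transport operators on the structural connectome.

A connectome here is a directed, weighted region-by-region matrix ``W`` in
which ``W[i, j]`` is the strength of the axonal projection from region ``j``
to region ``i``.  Pathology transport along such a graph is modelled with the
out-degree graph Laplacian

    L[i, j] = -W[i, j] + delta_ij * sum_k W[k, i]

whose columns sum to zero, so that pure diffusion conserves total pathology.
Four transport hypotheses are supported: anterograde (spread with the
projection direction, operator built from ``W``), retrograde (against the
projection direction, built from ``W.T``), bidirectional (both, each with its
own rate), and a spatial "Euclidean" control in which anatomy is replaced by a
symmetric distance kernel on region centroids.

The module also provides the two null models used to probe whether a fitted
model depends on the real anatomy: weight-preserving edge rewiring and seed
relocation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Connectome",
    "TransportOperator",
    "build_laplacian",
    "make_transport",
    "rewire_null",
    "random_seed_region",
]

TRANSPORT_MODES = ("retrograde", "anterograde", "bidirectional", "euclidean")


@dataclass
class Connectome:
    """Directed weighted connectivity with hemisphere-tagged regions.

    Parameters
    ----------
    region_ids : sequence of str
        Unique region labels; hemisphere is conventionally encoded as an
        ``_ipsi`` / ``_contra`` suffix.
    W : ndarray, shape (N, N)
        Nonnegative weights, ``W[i, j]`` = projection strength j -> i.
        The diagonal is zeroed on construction (self-projections carry no
        transport and cancel in the Laplacian anyway).
    hemisphere : sequence of str, optional
        Per-region tag (``ipsi``/``contra``).  If omitted it is parsed from
        the label suffix where possible.
    coords : ndarray, shape (N, 3), optional
        Region centroids, required only for Euclidean transport.
    """

    region_ids: Sequence[str]
    W: np.ndarray
    hemisphere: Sequence[str] | None = None
    coords: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.region_ids = list(map(str, self.region_ids))
        W = np.asarray(self.W, dtype=float)
        if W.ndim != 2 or W.shape[0] != W.shape[1]:
            raise ValueError(f"W must be square, got shape {W.shape}")
        if W.shape[0] != len(self.region_ids):
            raise ValueError(
                f"{len(self.region_ids)} region labels for a "
                f"{W.shape[0]}x{W.shape[1]} matrix"
            )
        if not np.all(np.isfinite(W)):
            raise ValueError("W contains non-finite entries")
        if np.any(W < 0):
            raise ValueError("W contains negative weights")
        if len(set(self.region_ids)) != len(self.region_ids):
            dup = sorted({r for r in self.region_ids if self.region_ids.count(r) > 1})
            raise ValueError(f"duplicate region labels: {dup}")
        W = W.copy()
        np.fill_diagonal(W, 0.0)
        self.W = W
        if self.hemisphere is None:
            self.hemisphere = [_parse_hemisphere(r) for r in self.region_ids]
        else:
            self.hemisphere = [str(h) for h in self.hemisphere]
        if self.coords is not None:
            coords = np.asarray(self.coords, dtype=float)
            if coords.shape != (self.n_regions, 3):
                raise ValueError("coords must have shape (N, 3)")
            self.coords = coords

    @property
    def n_regions(self) -> int:
        return self.W.shape[0]

    def index_of(self, labels: Iterable[str]) -> np.ndarray:
        """Map region labels to integer indices, raising on unknown labels."""
        lut = {r: i for i, r in enumerate(self.region_ids)}
        out = []
        for lab in labels:
            if lab not in lut:
                raise KeyError(f"unknown region label: {lab!r}")
            out.append(lut[lab])
        return np.asarray(out, dtype=int)

    def hemisphere_pairs(self) -> dict[str, tuple[int, int]]:
        """Base label -> (index in each hemisphere) for mirrored connectomes.

        Only regions present in both hemispheres are returned.
        """
        by_base: dict[str, dict[str, int]] = {}
        for i, (lab, hemi) in enumerate(zip(self.region_ids, self.hemisphere)):
            base = _strip_hemisphere(lab)
            by_base.setdefault(base, {})[hemi] = i
        return {
            base: (d["ipsi"], d["contra"])
            for base, d in by_base.items()
            if "ipsi" in d and "contra" in d
        }


@dataclass
class TransportOperator:
    """A transport hypothesis realised as one (or two) graph Laplacians."""

    mode: str
    L_primary: np.ndarray
    L_secondary: np.ndarray | None = None
    region_ids: Sequence[str] = field(default_factory=list)

    @property
    def n_regions(self) -> int:
        return self.L_primary.shape[0]


def _parse_hemisphere(label: str) -> str:
    if label.endswith("_ipsi"):
        return "ipsi"
    if label.endswith("_contra"):
        return "contra"
    return "ipsi"


def _strip_hemisphere(label: str) -> str:
    for suf in ("_ipsi", "_contra"):
        if label.endswith(suf):
            return label[: -len(suf)]
    return label


def build_laplacian(W: np.ndarray) -> np.ndarray:
    """Out-degree graph Laplacian ``L = -W + diag(out-strengths)``.

    The out-strength of region ``i`` is the column sum ``sum_k W[k, i]``
    (total outgoing projection weight).  The diagonal of ``W`` is zeroed
    first, after which every column of ``L`` sums to zero exactly, which is
    what makes linear diffusion on the graph mass-conserving.
    """
    W = np.asarray(W, dtype=float)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ValueError(f"W must be square, got shape {W.shape}")
    if np.any(W < 0) or not np.all(np.isfinite(W)):
        raise ValueError("W must be nonnegative and finite")
    W = W.copy()
    np.fill_diagonal(W, 0.0)
    return -W + np.diag(W.sum(axis=0))


def _euclidean_weights(
    coords: np.ndarray, length_scale: float | None = None
) -> np.ndarray:
    """Symmetric distance-kernel weight matrix on region centroids.

    Default kernel is inverse distance ``1/d``; with ``length_scale`` an
    exponential kernel ``exp(-d/length_scale)`` is used instead.
    """
    diff = coords[:, None, :] - coords[None, :, :]
    d = np.sqrt((diff**2).sum(axis=-1))
    n = d.shape[0]
    W = np.zeros_like(d)
    off = ~np.eye(n, dtype=bool)
    if np.any(d[off] == 0):
        raise ValueError("coincident region centroids; Euclidean kernel undefined")
    if length_scale is None:
        W[off] = 1.0 / d[off]
    else:
        if length_scale <= 0:
            raise ValueError("length_scale must be positive")
        W[off] = np.exp(-d[off] / length_scale)
    return W


def make_transport(
    conn: Connectome, mode: str, length_scale: float | None = None
) -> TransportOperator:
    """Build the Laplacian operator(s) for one of the four transport modes.

    retrograde    Laplacian of ``W.T`` (spread against projections)
    anterograde   Laplacian of ``W``
    bidirectional both, ``L_primary`` retrograde and ``L_secondary``
                  anterograde, each paired with its own rate downstream
    euclidean     Laplacian of a symmetric distance kernel (needs coords)
    """
    if mode not in TRANSPORT_MODES:
        raise ValueError(f"mode must be one of {TRANSPORT_MODES}, got {mode!r}")
    if mode == "anterograde":
        L, L2 = build_laplacian(conn.W), None
    elif mode == "retrograde":
        L, L2 = build_laplacian(conn.W.T), None
    elif mode == "bidirectional":
        L, L2 = build_laplacian(conn.W.T), build_laplacian(conn.W)
    else:  # euclidean
        if conn.coords is None:
            raise ValueError("Euclidean transport requires region coordinates")
        L, L2 = build_laplacian(_euclidean_weights(conn.coords, length_scale)), None
    return TransportOperator(mode=mode, L_primary=L, L_secondary=L2,
                             region_ids=list(conn.region_ids))


def rewire_null(
    conn: Connectome, rng_seed: int, method: str = "shuffle"
) -> Connectome:
    """Topology null model: randomly relocate the weighted edges.

    ``method="shuffle"`` (default) places the exact multiset of nonzero edge
    weights on uniformly chosen off-diagonal cells, preserving edge count and
    the weight distribution but not degrees.  ``method="degree_preserving"``
    performs directed double-edge swaps, additionally preserving each
    region's in- and out-degree sequence.
    """
    n = conn.n_regions
    if n < 3:
        raise ValueError("rewiring needs at least 3 regions")
    rng = np.random.default_rng(rng_seed)
    W = conn.W
    if method == "shuffle":
        weights = W[W > 0]
        k = weights.size
        off = [(i, j) for i in range(n) for j in range(n) if i != j]
        if k > len(off):
            raise ValueError("more edges than off-diagonal cells")
        pick = rng.choice(len(off), size=k, replace=False)
        weights = rng.permutation(weights)
        Wn = np.zeros_like(W)
        for w, p in zip(weights, pick):
            Wn[off[p]] = w
    elif method == "degree_preserving":
        Wn = W.copy()
        edges = list(zip(*np.nonzero(Wn)))
        n_swaps = 10 * len(edges)
        for _ in range(n_swaps):
            (a, b), (c, d) = (edges[rng.integers(len(edges))] for _ in range(2))
            # swap targets: (a,b),(c,d) -> (a,d),(c,b); keeps degrees
            if a == c or b == d or a == d or c == b:
                continue
            if Wn[a, d] != 0 or Wn[c, b] != 0:
                continue
            Wn[a, d], Wn[c, b] = Wn[a, b], Wn[c, d]
            Wn[a, b] = Wn[c, d] = 0.0
            edges = list(zip(*np.nonzero(Wn)))
    else:
        raise ValueError(f"unknown rewiring method {method!r}")
    return Connectome(
        region_ids=list(conn.region_ids),
        W=Wn,
        hemisphere=list(conn.hemisphere),
        coords=None if conn.coords is None else conn.coords.copy(),
    )


def random_seed_region(
    conn: Connectome, true_seeds: Iterable[int] | Iterable[str], rng_seed: int
) -> list[int]:
    """Seed-location null: a random region set of the same size.

    Returns indices of a uniformly drawn set disjoint from the true seeds.
    """
    seeds = list(true_seeds)
    if len(seeds) == 0:
        raise ValueError("need at least one true seed")
    if seeds and isinstance(seeds[0], str):
        seeds = list(conn.index_of(seeds))
    seeds = set(int(s) for s in seeds)
    candidates = [i for i in range(conn.n_regions) if i not in seeds]
    if len(candidates) < len(seeds):
        raise ValueError(
            f"cannot draw {len(seeds)} non-seed regions out of {conn.n_regions}"
        )
    rng = np.random.default_rng(rng_seed)
    return sorted(rng.choice(candidates, size=len(seeds), replace=False).tolist())
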