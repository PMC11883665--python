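"""Partition a predicted model into rigid structural units ("slices").

Two families of methods are provided.  Coordinate clustering (k-means,
BIRCH — the default — and agglomerative, plus a density-based auto method)
exploits the spatial compactness of domains by clustering Calpha positions
in 3-D.  PAE-graph clustering builds a residue graph whose edges connect
pairs with low predicted aligned error and finds communities by greedy
modularity maximisation, so the number of units is determined
automatically and coordinates are never consulted.

Slices are canonically numbered 1..k by descending residue count (ties by
the earliest residue), can be merged down to a requested maximum number of
splits by agglomerative clustering of slice centroids, and are exported as
independent coordinate files with a colour key.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np
from sklearn.cluster import DBSCAN, AgglomerativeClustering, Birch, KMeans

from .structures import (CaTable, PAEMatrix, PredictedModel, ResidueKey,
                         ValidationError, ca_coordinates, write_model)

logger = logging.getLogger(__name__)

__all__ = [
    "COORDINATE_METHODS",
    "SliceAssignment",
    "Slice",
    "slice_by_coordinates",
    "slice_by_pae",
    "merge_to_max_splits",
    "slice_range",
    "slice_multi",
    "export_slices",
]

COORDINATE_METHODS = ("kmeans", "birch", "agglomerative", "auto_density")
DEFAULT_METHOD = "birch"
#: Communities smaller than this are merged into their closest unit.
MIN_SLICE_SIZE = 10

# 20 visually distinct colours, reused cyclically for k > 20.
_PALETTE = [
    "#1f77b4", "#ff7f0e", "#2ca02c", "#d62728", "#9467bd", "#8c564b",
    "#e377c2", "#7f7f7f", "#bcbd22", "#17becf", "#aec7e8", "#ffbb78",
    "#98df8a", "#ff9896", "#c5b0d5", "#c49c94", "#f7b6d2", "#c7c7c7",
    "#dbdb8d", "#9edae5",
]


class ParameterError(ValueError):
    """Invalid clustering parameters."""


class DegenerateInputError(ValueError):
    """Geometry carries no clusterable structure (e.g. coincident atoms)."""


@dataclass
class SliceAssignment:
    """A residue -> structural-unit partition of one model.

    ``labels`` maps each clustered residue key to a slice index in 1..k;
    slice 1 is the largest unit (ties broken by the earliest residue).
    """

    model_id: str
    labels: dict[ResidueKey, int]
    k: int
    method: str
    parameters: dict = field(default_factory=dict)
    seed: int | None = None

    def members(self, index: int) -> list[ResidueKey]:
        return [key for key, lab in self.labels.items() if lab == index]

    def validate(self) -> None:
        labs = set(self.labels.values())
        if labs != set(range(1, self.k + 1)):
            raise ValidationError(
                f"slice indices {sorted(labs)} are not 1..{self.k}")


@dataclass
class Slice:
    parent_model_id: str
    slice_index: int
    residue_keys: list[ResidueKey]
    model: PredictedModel

    @property
    def slice_id(self) -> str:
        return f"{self.parent_model_id}_slice{self.slice_index}"


def _canonical_labels(raw: np.ndarray, keys: list[ResidueKey],
                      model_id: str, method: str, parameters: dict,
                      seed: int | None) -> SliceAssignment:
    """Relabel raw cluster ids to the canonical 1..k ordering."""
    order = {}
    sizes: dict[int, int] = {}
    for pos, lab in enumerate(raw):
        lab = int(lab)
        sizes[lab] = sizes.get(lab, 0) + 1
        order.setdefault(lab, pos)  # position of first member in model order
    ranked = sorted(sizes, key=lambda lab: (-sizes[lab], order[lab]))
    remap = {lab: i + 1 for i, lab in enumerate(ranked)}
    labels = {key: remap[int(lab)] for key, lab in zip(keys, raw)}
    assignment = SliceAssignment(model_id, labels, len(ranked), method,
                                 parameters, seed)
    assignment.validate()
    return assignment


def slice_by_coordinates(model: PredictedModel,
                         method: str = DEFAULT_METHOD,
                         n_clusters: int | str = 2,
                         seed: int | None = 0) -> SliceAssignment:
    """Cluster Calpha coordinates into ``n_clusters`` structural units.

    ``method`` is one of kmeans/birch/agglomerative (manual cluster count)
    or auto_density (DBSCAN-style; ``n_clusters`` ignored).  Deterministic
    for a fixed seed.
    """
    if method not in COORDINATE_METHODS:
        raise ParameterError(f"unknown method {method!r}; "
                             f"choose from {COORDINATE_METHODS}")
    table = ca_coordinates(model)
    n = len(table.keys)
    params: dict = {"method": method}
    if method != "auto_density":
        if not isinstance(n_clusters, int) or n_clusters < 1 or n_clusters > n:
            raise ParameterError(
                f"n_clusters={n_clusters} invalid for {n} residues")
        params["n_clusters"] = n_clusters
    span = np.ptp(table.coords, axis=0)
    if np.all(span < 1e-6) and n > 1:
        raise DegenerateInputError("all Calpha coordinates coincide")

    if method == "kmeans":
        raw = KMeans(n_clusters=n_clusters, random_state=seed,
                     n_init=10).fit_predict(table.coords)
    elif method == "birch":
        raw = Birch(n_clusters=n_clusters,
                    threshold=2.5).fit_predict(table.coords)
    elif method == "agglomerative":
        if n_clusters == n:
            raw = np.arange(n)
        else:
            raw = AgglomerativeClustering(
                n_clusters=n_clusters, linkage="ward").fit_predict(table.coords)
    else:  # auto_density
        params.update({"eps": 8.0, "min_samples": 5})
        raw = DBSCAN(eps=8.0, min_samples=5).fit_predict(table.coords)
        raw = _assign_noise_points(raw, table.coords)
    return _canonical_labels(np.asarray(raw), table.keys, model.model_id,
                             method, params, seed)


def _assign_noise_points(raw: np.ndarray, coords: np.ndarray) -> np.ndarray:
    """Attach DBSCAN noise points (-1) to the nearest cluster centroid."""
    raw = raw.copy()
    labs = sorted(set(raw) - {-1})
    if not labs:  # everything is noise: one slice
        return np.zeros(len(raw), dtype=int)
    centroids = np.array([coords[raw == lab].mean(axis=0) for lab in labs])
    for i in np.where(raw == -1)[0]:
        raw[i] = labs[int(np.argmin(np.linalg.norm(centroids - coords[i], axis=1)))]
    return raw


def slice_by_pae(pae: PAEMatrix, model: PredictedModel,
                 pae_cutoff: float = 5.0, resolution_param: float = 1.0,
                 seed: int | None = 0,
                 min_slice_size: int = MIN_SLICE_SIZE) -> SliceAssignment:
    """Partition residues by community detection on the PAE graph.

    Residue pairs whose symmetrised PAE (element-wise minimum of the two
    directions) falls below ``pae_cutoff`` are joined by an edge of weight
    1/max(PAE, 0.2); greedy modularity maximisation yields an automatically
    determined number of units.  Communities smaller than
    ``min_slice_size`` are absorbed into the community with the lowest mean
    PAE to them, so the partition depends on the PAE alone, never on
    coordinates.
    """
    keys = model.residue_keys()
    if pae.n != len(keys):
        raise ValidationError(
            f"PAE is {pae.n}x{pae.n} but model has {len(keys)} residues")
    n = pae.n
    sym = np.minimum(pae.values, pae.values.T)
    graph = nx.Graph()
    graph.add_nodes_from(range(n))
    ii, jj = np.nonzero(np.triu(sym < pae_cutoff, k=1))
    for i, j in zip(ii.tolist(), jj.tolist()):
        graph.add_edge(i, j, weight=1.0 / max(sym[i, j], 0.2))
    communities = nx.community.greedy_modularity_communities(
        graph, weight="weight", resolution=resolution_param)
    raw = np.full(n, -1, dtype=int)
    for lab, members in enumerate(communities):
        raw[list(members)] = lab
    raw = _merge_small_communities(raw, sym, min_slice_size)
    return _canonical_labels(raw, keys, model.model_id, "pae",
                             {"pae_cutoff": pae_cutoff,
                              "resolution_param": resolution_param,
                              "min_slice_size": min_slice_size}, seed)


def _merge_small_communities(raw: np.ndarray, sym: np.ndarray,
                             min_size: int) -> np.ndarray:
    """Absorb undersized communities into their lowest-mean-PAE neighbour."""
    raw = raw.copy()
    while True:
        labs, counts = np.unique(raw, return_counts=True)
        if len(labs) <= 1:
            break
        small = [lab for lab, c in zip(labs, counts) if c < min_size]
        if not small:
            break
        # merge the smallest first
        lab = min(small, key=lambda l: (counts[list(labs).index(l)], l))
        members = raw == lab
        best, best_affinity = None, np.inf
        for other in labs:
            if other == lab:
                continue
            affinity = float(sym[np.ix_(members, raw == other)].mean())
            if affinity < best_affinity:
                best, best_affinity = other, affinity
        raw[members] = best
    return raw


def _slice_centroids(assignment: SliceAssignment,
                     coords: CaTable) -> np.ndarray:
    pos = {key: i for i, key in enumerate(coords.keys)}
    centroids = []
    for idx in range(1, assignment.k + 1):
        rows = [pos[k] for k in assignment.members(idx) if k in pos]
        if not rows:
            raise ValidationError(f"slice {idx} has no Calpha coordinates")
        centroids.append(coords.coords[rows].mean(axis=0))
    return np.array(centroids)


def merge_to_max_splits(assignment: SliceAssignment, coords: CaTable,
                        max_splits: int) -> SliceAssignment:
    """Merge slices down to ``max_splits`` units by clustering centroids.

    Each slice's Calpha centroid is computed and the centroids are
    agglomeratively clustered (single linkage, Euclidean) into
    ``max_splits`` groups; slices in one group are unioned.  Identity when
    k <= max_splits.
    """
    if max_splits < 1:
        raise ParameterError("max_splits must be >= 1")
    if assignment.k <= max_splits:
        return assignment
    centroids = _slice_centroids(assignment, coords)
    if max_splits == 1:
        groups = np.zeros(assignment.k, dtype=int)
    else:
        groups = AgglomerativeClustering(
            n_clusters=max_splits, linkage="single").fit_predict(centroids)
    raw_keys = list(assignment.labels)
    raw = np.array([groups[assignment.labels[k] - 1] for k in raw_keys])
    merged = _canonical_labels(raw, raw_keys, assignment.model_id,
                               assignment.method,
                               dict(assignment.parameters,
                                    merged_to=max_splits),
                               assignment.seed)
    return merged


def slice_range(model: PredictedModel, method: str = DEFAULT_METHOD,
                min_splits: int = 1, max_splits: int = 1,
                seed: int | None = 0,
                pae: PAEMatrix | None = None) -> list[SliceAssignment]:
    """One assignment per split count in [min_splits, max_splits].

    Manual coordinate methods are re-run per k.  For PAE/auto methods the
    automatic assignment is returned, plus centroid-merged variants for
    each requested k below the automatic one.
    """
    n = model.n_residues
    if not (1 <= min_splits <= max_splits <= n):
        raise ParameterError(
            f"invalid split range [{min_splits}, {max_splits}] for "
            f"{n} residues")
    if method in ("kmeans", "birch", "agglomerative"):
        return [slice_by_coordinates(model, method, k, seed)
                for k in range(min_splits, max_splits + 1)]
    if method == "pae":
        if pae is None:
            raise ParameterError("PAE matrix required for method 'pae'")
        auto = slice_by_pae(pae, model, seed=seed)
    else:
        auto = slice_by_coordinates(model, method, seed=seed)
    table = ca_coordinates(model)
    out = [auto]
    for k in range(min_splits, min(max_splits + 1, auto.k)):
        out.append(merge_to_max_splits(auto, table, k))
    return out


def slice_multi(models: Sequence[PredictedModel],
                per_model_splits: Sequence[int],
                method: str = DEFAULT_METHOD,
                seed: int | None = 0) -> list[SliceAssignment]:
    """Independent assignments for several models with per-model counts."""
    if len(models) != len(per_model_splits):
        raise ParameterError(
            f"{len(models)} models but {len(per_model_splits)} split counts")
    if any(s < 1 for s in per_model_splits):
        raise ParameterError("split counts must be >= 1")
    return [slice_by_coordinates(m, method, k, seed)
            for m, k in zip(models, per_model_splits)]


def _sequence_segments(keys: list[ResidueKey]) -> int:
    """Number of sequence-contiguous runs in a slice's residue keys."""
    segs = 0
    prev: ResidueKey | None = None
    for key in sorted(keys):
        if prev is None or key[0] != prev[0] or key[1] - prev[1] > 1:
            segs += 1
        prev = key
    return segs


def export_slices(model: PredictedModel, assignment: SliceAssignment,
                  outdir: str | Path, fmt: str = "pdb") -> list[Slice]:
    """Write one coordinate file per slice plus a tab-separated colour key.

    Slices spanning two or more sequence-discontiguous segments are flagged
    as fragmented in the key (such slices can pack poorly as search
    models).
    """
    if assignment.model_id != model.model_id:
        raise ValidationError(
            f"assignment belongs to {assignment.model_id!r}, "
            f"not {model.model_id!r}")
    outdir = Path(outdir)
    try:
        outdir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create output directory {outdir}: {exc}") from exc

    slices: list[Slice] = []
    key_rows = []
    order = {key: i for i, key in enumerate(model.residue_keys())}
    for idx in range(1, assignment.k + 1):
        keys = sorted(assignment.members(idx), key=order.__getitem__)
        sub = model.select(keys, model_id=f"{model.model_id}_slice{idx}")
        path = outdir / f"{model.model_id}_slice{idx}.{fmt}"
        write_model(sub, path)
        segs = _sequence_segments(keys)
        colour = _PALETTE[(idx - 1) % len(_PALETTE)]
        key_rows.append({
            "filename": path.name,
            "slice_index": idx,
            "colour": colour,
            "n_residues": len(keys),
            "n_segments": segs,
            "fragmented": "yes" if segs >= 2 else "no",
        })
        slices.append(Slice(model.model_id, idx, keys, sub))
    key_path = outdir / f"{model.model_id}_colour_key.tsv"
    with open(key_path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(key_rows[0]), delimiter="\t")
        writer.writeheader()
        writer.writerows(key_rows)
    logger.info("wrote %d slices + colour key to %s", len(slices), outdir)
    return slices
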