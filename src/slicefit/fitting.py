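"""Rigid-body placement of slices into a density map.

The fitting engine performs an exhaustive rotational and translational
search: orientations are sampled on a deterministic quasi-uniform SO(3)
grid, and for each orientation the slice's simulated density is scanned
against the target map at every integer-voxel translation by FFT
cross-correlation (the cyclic normalized cross-correlation; its top score
matches a direct sliding-window scan).  Top placements are re-scored by a
local correlation over the slice footprint.

Around the fitting engine sits the placement loop: each fitted slice is
scored (see :mod:`slicefit.density`), gated by the trained classifier, and
surviving placements are checked pairwise for steric clashes — a clash is
declared when more than 5% of the atoms of the smaller model lie within
3.8 A (one Calpha-Calpha step) of the other model, computed with a
ball-tree spatial index; the placement with the lower classifier
probability is discarded.  The combined solution is scored by a local
cross-correlation and assigned a resolution-dependent assessment band
(good fit / indeterminate / likely misfit).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.neighbors import BallTree

from .classifier import ClassifierModel, classify
from .density import (DensityMap, GeometryError, cross_correlation,
                      feature_vector, simulate_on_grid)
from .slicer import Slice
from .structures import PredictedModel

logger = logging.getLogger(__name__)

__all__ = [
    "Placement",
    "ClashReport",
    "PlacementSet",
    "so3_grid",
    "fit_translation",
    "fit_exhaustive",
    "clash_fraction",
    "resolve_clashes",
    "run_pipeline",
    "assessment_band",
]

CLASH_DISTANCE = 3.8          # A, one Calpha-Calpha step
CLASH_FRACTION_THRESHOLD = 0.05
BBOX_MARGIN = 2.0             # A, margin for the bounding-box pre-check
FOOTPRINT_LEVEL = 1e-4        # fraction of peak density defining a footprint

#: cross-correlation assessment bands: resolution range -> (good, misfit)
CC_BANDS = {
    (4.5, 6.0): (0.507, 0.408),
    (6.0, np.inf): (0.559, 0.4345),
}


@dataclass
class Placement:
    """A rigid pose of a slice: y = rotation @ x + translation."""

    slice_ref: str
    rotation: np.ndarray       # (3, 3), proper rotation
    translation: np.ndarray    # (3,), Angstrom
    score: float               # local (footprint) CC of the fit
    probability: float | None = None
    fit_cc: float | None = None  # global translational-search CC

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)
        if not np.allclose(self.rotation.T @ self.rotation, np.eye(3),
                           atol=1e-8):
            raise ValueError("rotation is not orthonormal")
        if abs(np.linalg.det(self.rotation) - 1.0) > 1e-8:
            raise ValueError("rotation determinant is not +1")

    def apply(self, xyz: np.ndarray) -> np.ndarray:
        return np.asarray(xyz) @ self.rotation.T + self.translation

    def place(self, model: PredictedModel) -> PredictedModel:
        """The model with this pose applied to every atom."""
        out = model.copy()
        for _, res in out.iter_residues():
            for atom in res.atoms:
                atom.xyz = self.apply(atom.xyz)
        return out


@dataclass
class ClashReport:
    pair: tuple[str, str]
    fraction: float
    clash: bool
    winner: str | None

    def to_dict(self) -> dict:
        return {"pair": list(self.pair), "fraction": self.fraction,
                "clash": self.clash, "winner": self.winner}


@dataclass
class PlacementSet:
    accepted: list[Placement]
    rejected: list[tuple[Placement, str]]
    combined_cc: float | None
    assessment_band: str | None
    clash_reports: list[ClashReport] = field(default_factory=list)
    placed_models: dict = field(default_factory=dict)  # slice_ref -> model


# ---------------------------------------------------------------------------
# rotation sampling

def _fibonacci_sphere(n: int) -> np.ndarray:
    i = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + np.sqrt(5.0)) * i
    return np.column_stack([np.sin(phi) * np.cos(theta),
                            np.sin(phi) * np.sin(theta),
                            np.cos(phi)])


def so3_grid(angular_step: float) -> np.ndarray:
    """Deterministic quasi-uniform rotation grid, identity first.

    Viewing directions are Fibonacci-sphere points at roughly
    ``angular_step`` spacing; each is combined with in-plane twists at the
    same step.  No randomness, so runs reproduce without seeds.
    """
    if not 10.0 <= angular_step <= 90.0:
        raise ValueError(f"angular_step must be in [10, 90] deg, "
                         f"got {angular_step}")
    step = np.radians(angular_step)
    n_dir = max(1, int(np.ceil(4.0 * np.pi / step ** 2)))
    dirs = _fibonacci_sphere(n_dir)
    twists = np.arange(0.0, 2.0 * np.pi - 1e-9, step)
    mats = [np.eye(3)]
    z = np.array([0.0, 0.0, 1.0])
    for d in dirs:
        # rotation taking z to d
        v = np.cross(z, d)
        c = float(np.dot(z, d))
        if np.linalg.norm(v) < 1e-12:
            align = np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
        else:
            vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]],
                           [-v[1], v[0], 0]])
            align = np.eye(3) + vx + vx @ vx / (1.0 + c)
        for t in twists:
            ct, st = np.cos(t), np.sin(t)
            rz = np.array([[ct, -st, 0], [st, ct, 0], [0, 0, 1]])
            mats.append(align @ rz)
    return np.array(mats)


# ---------------------------------------------------------------------------
# translational search

def _translation_scores(slice_map: DensityMap,
                        target_map: DensityMap) -> np.ndarray:
    """Pearson correlation for every cyclic integer-voxel shift (FFT)."""
    a = slice_map.grid.astype(np.float64)
    b = target_map.grid.astype(np.float64)
    a0 = a - a.mean()
    b0 = b - b.mean()
    sa = np.sqrt((a0 * a0).sum())
    sb = np.sqrt((b0 * b0).sum())
    if sa == 0 or sb == 0:
        raise ValueError("translational search undefined for a constant map")
    # corr[t] = sum_x a0[x - t] * b0[x] = IFFT(FFT(a0)* . FFT(b0))[t]
    corr = np.fft.ifftn(np.conj(np.fft.fftn(a0)) * np.fft.fftn(b0)).real
    return corr / (sa * sb)


def _parabolic_offset(scores: np.ndarray, peak: np.ndarray) -> np.ndarray:
    """Sub-voxel peak offset by per-axis parabolic interpolation."""
    delta = np.zeros(3)
    for ax in range(3):
        lo = scores[tuple(np.mod(peak - np.eye(3, dtype=int)[ax],
                                 scores.shape))]
        hi = scores[tuple(np.mod(peak + np.eye(3, dtype=int)[ax],
                                 scores.shape))]
        c = scores[tuple(peak)]
        denom = lo - 2.0 * c + hi
        if denom < 0:
            delta[ax] = float(np.clip(0.5 * (lo - hi) / denom, -0.5, 0.5))
    return delta


def fit_translation(slice_map: DensityMap, target_map: DensityMap,
                    top_n: int | None = None
                    ) -> list[tuple[np.ndarray, float]]:
    """Rank every integer-voxel translation by normalized cross-correlation.

    The score at shift t is the Pearson correlation between the slice map
    cyclically shifted by t voxels and the target, computed for all shifts
    at once in the Fourier domain.  Returned translations are in Angstrom
    (signed, wrapped to the half-open grid range), best first.
    """
    if slice_map.shape != target_map.shape:
        raise GeometryError(
            f"slice grid {slice_map.shape} does not match target "
            f"{target_map.shape}; simulate the slice on the target geometry")
    scores = _translation_scores(slice_map, target_map)
    flat = np.argsort(scores, axis=None)[::-1]
    if top_n is not None:
        flat = flat[:top_n]
    shape = np.array(slice_map.shape)
    out = []
    for f in flat:
        t = np.array(np.unravel_index(f, slice_map.shape), dtype=int)
        signed = np.where(t >= shape // 2 + shape % 2, t - shape, t)
        out.append((signed * slice_map.voxel_size, float(scores.flat[f])))
    return out


def _local_cc(sim: DensityMap, target: DensityMap) -> float:
    mask = sim.grid > FOOTPRINT_LEVEL * float(sim.grid.max())
    if not mask.any():
        return -1.0
    try:
        return cross_correlation(sim, target, mask=mask)
    except ValueError:
        return -1.0


def fit_exhaustive(slc: Slice | PredictedModel, dmap: DensityMap,
                   angular_step: float = 30.0, seed: int | None = None,
                   top_n: int = 5,
                   resolution: float | None = None) -> list[Placement]:
    """Exhaustive rotational + translational search of a slice in a map.

    For each orientation on the SO(3) grid the slice is rotated about its
    centroid, simulated on the target geometry and scanned over all
    integer-voxel translations; the best ``top_n`` poses overall are
    returned with their local footprint CC as the placement score.
    Deterministic: the rotation grid is fixed and FFT scores are exact.
    """
    model = slc.model if isinstance(slc, Slice) else slc
    ref = slc.slice_id if isinstance(slc, Slice) else model.model_id
    if model.n_atoms == 0:
        raise ValueError(f"slice {ref} is empty")
    res = resolution or dmap.nominal_resolution
    coords = model.atom_coordinates()
    centroid = coords.mean(axis=0)
    box_centre = dmap.origin + (np.array(dmap.shape) - 1) * dmap.voxel_size / 2.0
    candidates: list[tuple[float, np.ndarray, np.ndarray]] = []
    centred = coords - centroid
    for rot in so3_grid(angular_step):
        placed = centred @ rot.T + box_centre
        sim = dmap.empty_like()
        sim.nominal_resolution = res
        tmp = sim.grid.astype(np.float64)
        from .density import _gaussian_sigma, _splat_atoms
        _splat_atoms(tmp, placed, sim.origin, sim.voxel_size,
                     _gaussian_sigma(res))
        sim.grid = tmp.astype(np.float32)
        scores = _translation_scores(sim, dmap)
        peak = np.array(np.unravel_index(np.argmax(scores), scores.shape))
        score = float(scores[tuple(peak)])
        shape = np.array(scores.shape)
        signed = np.where(peak >= shape // 2 + shape % 2, peak - shape, peak)
        # parabolic sub-voxel refinement of the correlation peak
        frac = signed + _parabolic_offset(scores, peak)
        shift = frac * dmap.voxel_size
        # pose: y = rot @ (x - centroid) + box_centre + shift
        translation = box_centre + shift - rot @ centroid
        candidates.append((score, rot, translation))
    candidates.sort(key=lambda c: -c[0])
    placements = []
    for score, rot, translation in candidates[:top_n]:
        pose = Placement(ref, rot, translation, score=0.0, fit_cc=score)
        placed_model = pose.place(model)
        sim = simulate_on_grid(placed_model, dmap, res)
        pose.score = _local_cc(sim, dmap)
        placements.append(pose)
    placements.sort(key=lambda p: -p.score)
    return placements


# ---------------------------------------------------------------------------
# clash checking

def _bbox(coords: np.ndarray, margin: float = BBOX_MARGIN
          ) -> tuple[np.ndarray, np.ndarray]:
    return coords.min(axis=0) - margin, coords.max(axis=0) + margin


def _bboxes_intersect(a: np.ndarray, b: np.ndarray) -> bool:
    (alo, ahi), (blo, bhi) = _bbox(a), _bbox(b)
    return bool(np.all(alo <= bhi) and np.all(blo <= ahi))


def clash_fraction(a: np.ndarray, b: np.ndarray,
                   distance: float = CLASH_DISTANCE) -> float:
    """Fraction of the smaller atom set with any neighbour within ``distance``.

    Exact: the ball-tree radius query returns the same neighbour sets as an
    all-pairs distance scan.
    """
    a = np.asarray(a, dtype=float).reshape(-1, 3)
    b = np.asarray(b, dtype=float).reshape(-1, 3)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("clash check requires two non-empty atom sets")
    small, large = (a, b) if len(a) <= len(b) else (b, a)
    tree = BallTree(large)
    counts = tree.query_radius(small, r=distance, count_only=True)
    return float(np.count_nonzero(counts) / len(small))


def resolve_clashes(placements: Sequence[Placement],
                    atom_sets: dict[str, np.ndarray],
                    fraction_threshold: float = CLASH_FRACTION_THRESHOLD,
                    distance: float = CLASH_DISTANCE
                    ) -> tuple[list[Placement], list[Placement],
                               list[ClashReport]]:
    """Greedy clash resolution in descending classifier probability.

    A pair clashes when the overlap fraction strictly exceeds
    ``fraction_threshold``; the lower-probability placement loses.  A
    probability tie is broken in favour of the larger (more atoms)
    placement, then by slice id.  The kept set is pairwise non-clashing.
    """
    missing = [p.slice_ref for p in placements if p.probability is None]
    if missing:
        raise ValueError(f"placements lack probabilities: {missing}")
    order = sorted(placements,
                   key=lambda p: (-p.probability,
                                  -len(atom_sets[p.slice_ref]), p.slice_ref))
    kept: list[Placement] = []
    discarded: list[Placement] = []
    reports: list[ClashReport] = []
    for cand in order:
        c_atoms = atom_sets[cand.slice_ref]
        clash = False
        for winner in kept:
            w_atoms = atom_sets[winner.slice_ref]
            if not _bboxes_intersect(c_atoms, w_atoms):
                continue
            frac = clash_fraction(c_atoms, w_atoms, distance)
            is_clash = frac > fraction_threshold
            reports.append(ClashReport(
                (winner.slice_ref, cand.slice_ref), frac, is_clash,
                winner.slice_ref if is_clash else None))
            if is_clash:
                clash = True
                break
        (discarded if clash else kept).append(cand)
    return kept, discarded, reports


# ---------------------------------------------------------------------------
# assessment + pipeline

def assessment_band(cc: float, resolution: float | None) -> str:
    """Resolution-dependent good-fit / indeterminate / misfit band for a CC.

    Bands exist for 4.5-6 A (good > 0.507, misfit < 0.408) and > 6 A
    (0.559 / 0.4345); below 4.5 A no band is defined and the call returns
    indeterminate with a logged note.
    """
    if not -1.0 <= cc <= 1.0:
        raise ValueError(f"CC {cc} outside [-1, 1]")
    if resolution is None or resolution < 4.5:
        logger.info("no CC assessment band defined below 4.5 A resolution")
        return "indeterminate"
    for (lo, hi), (good, misfit) in CC_BANDS.items():
        if lo <= resolution <= hi:
            if cc > good:
                return "good_fit"
            if cc < misfit:
                return "likely_misfit"
            return "indeterminate"
    return "indeterminate"


def _mask_out_atoms(dmap: DensityMap, coords: np.ndarray,
                    radius: float = 3.0) -> DensityMap:
    """Zero voxels within ``radius`` of any atom (fixed-model masking)."""
    from .density import _footprint_mask
    out = dmap.copy()
    out.grid[_footprint_mask(coords, dmap, radius)] = 0.0
    return out


def run_pipeline(slices: Sequence[Slice], dmap: DensityMap,
                 clf: ClassifierModel, mode: str = "parallel",
                 seed: int | None = None, angular_step: float = 30.0,
                 resolution: float | None = None) -> PlacementSet:
    """Fit slices into a map with classifier gating and clash resolution.

    Parallel mode fits every slice independently against the full map,
    gates each top placement with the classifier, then resolves clashes
    among the survivors.  Sequential mode fits slices in descending size
    order and masks each accepted placement's footprint out of the map
    before the next fit (fixed-model behaviour), so later slices cannot
    re-occupy claimed density.  The combined solution is scored by local
    CC and banded by resolution.
    """
    if mode not in ("parallel", "sequential"):
        raise ValueError(f"unknown mode {mode!r}")
    res = resolution or dmap.nominal_resolution
    if res is None:
        raise GeometryError("a nominal resolution is required")
    accepted: list[Placement] = []
    rejected: list[tuple[Placement, str]] = []
    reports: list[ClashReport] = []
    placed_models: dict[str, PredictedModel] = {}
    atom_sets: dict[str, np.ndarray] = {}

    def gate(slc: Slice, search_map: DensityMap) -> tuple[Placement, str | None]:
        top = fit_exhaustive(slc, search_map, angular_step, seed,
                             top_n=1, resolution=res)[0]
        placed = top.place(slc.model)
        features = feature_vector(placed, dmap, resolution=res)
        verdict, prob = classify(clf, features)
        top.probability = prob
        placed_models[top.slice_ref] = placed
        atom_sets[top.slice_ref] = placed.atom_coordinates()
        return top, None if verdict == "pass" else (
            f"classifier probability {prob:.3f} <= cutoff {clf.cutoff}")

    ordered = sorted(slices, key=lambda s: (-s.model.n_atoms, s.slice_id))
    if mode == "parallel":
        survivors = []
        for slc in ordered:
            placement, reason = gate(slc, dmap)
            if reason is None:
                survivors.append(placement)
            else:
                rejected.append((placement, reason))
        kept, lost, reports = resolve_clashes(survivors, atom_sets)
        accepted = kept
        rejected += [(p, "clash with a higher-probability placement")
                     for p in lost]
    else:
        work = dmap.copy()
        for slc in ordered:
            placement, reason = gate(slc, work)
            if reason is None:
                accepted.append(placement)
                work = _mask_out_atoms(work, atom_sets[placement.slice_ref])
            else:
                rejected.append((placement, reason))
        # post-hoc safety: accepted placements must be pairwise non-clashing
        kept, lost, reports = resolve_clashes(accepted, atom_sets)
        accepted = kept
        rejected += [(p, "clash with a higher-probability placement")
                     for p in lost]

    combined_cc = None
    band = None
    if accepted:
        combined = dmap.empty_like()
        combined.nominal_resolution = res
        acc = combined.grid.astype(np.float64)
        for p in accepted:
            acc += simulate_on_grid(placed_models[p.slice_ref], dmap,
                                    res).grid
        combined.grid = acc.astype(np.float32)
        combined_cc = _local_cc(combined, dmap)
        band = assessment_band(combined_cc, res)
    else:
        logger.warning("no slice passed the classifier gate")
    return PlacementSet(accepted, rejected, combined_cc, band, reports,
                        placed_models)
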