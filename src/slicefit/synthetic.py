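"""Seeded generators for multi-domain models, target maps and score rows.

Tests and examples need predicted-model-like inputs with known ground
truth: multi-domain Calpha traces with planted domain labels, confidence
profiles (high-pLDDT cores, low-pLDDT linkers), block-structured PAE
matrices, density maps rendered from known poses, and classifier training
rows with controllable class separation.  Everything here is a pure
function of its spec and seed.

The models are deliberately simplified: each domain is a self-avoiding
Calpha random walk confined to a sphere (radius scaling with the cube root
of its residue count), with dummy N/C/O/CB atoms at fixed offsets for
atom-count realism.  Physically realistic backbone geometry is out of
scope — clustering, fitting and scoring depend only on coarse shape.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .classifier import TrainingRow, TrainingSet
from .density import DensityMap, ScoreVector, simulate_on_grid
from .fitting import Placement
from .structures import (Atom, Chain, PAEMatrix, PredictedModel, Residue,
                         ScoreType)

__all__ = [
    "PlantedModelSpec",
    "ClassifierFixtureSpec",
    "make_planted_model",
    "make_target_map",
    "make_classifier_fixture",
    "FIXTURE_FEATURE_MEANS",
]

CA_STEP = 3.8          # A, consecutive Calpha distance
MIN_SEPARATION = 3.0   # A, non-consecutive Calpha exclusion
#: fixed local offsets for the dummy backbone/CB atoms, A
_DUMMY_ATOMS = {
    "N": np.array([-1.2, 0.6, 0.0]),
    "C": np.array([1.2, 0.5, 0.0]),
    "O": np.array([1.9, -0.5, 0.3]),
    "CB": np.array([-0.5, -1.3, 0.8]),
}

#: classifier-fixture feature means: (incorrect-class, correct-class)
FIXTURE_FEATURE_MEANS = {
    "fsc_avg": (0.30, 0.80),
    "mi": (0.30, 1.20),
    "cc": (0.35, 0.85),
    "smoc": (0.40, 0.90),
    "overlap_map": (0.25, 0.60),
    "overlap_model": (0.40, 0.95),
}
_FEATURE_CLIP = {
    "fsc_avg": (-1.0, 1.0), "mi": (0.0, np.inf), "cc": (-1.0, 1.0),
    "smoc": (0.0, 1.0), "overlap_map": (0.0, 1.0), "overlap_model": (0.0, 1.0),
}
#: PAE block parameters (mean, sd), A
_PAE_INTRA = (3.0, 0.5)
_PAE_INTER = (25.0, 3.0)
_PAE_LINKER = (12.0, 2.0)


@dataclass
class PlantedModelSpec:
    """Ground-truth layout of a synthetic multi-domain model."""

    n_domains: int = 2
    residues_per_domain: Sequence[int] = (60, 60)
    inter_centroid_separation: float = 40.0
    linker_length: int = 8
    #: ((core pLDDT mean, sd), (linker pLDDT mean, sd))
    confidence_profile: tuple = ((90.0, 4.0), (40.0, 5.0))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.inter_centroid_separation <= 0:
            raise ValueError("separation must be positive")
        if len(self.residues_per_domain) != self.n_domains:
            raise ValueError("residues_per_domain length must equal n_domains")
        if any(n < 10 for n in self.residues_per_domain):
            raise ValueError("domains must have at least 10 residues")


@dataclass
class ClassifierFixtureSpec:
    """Layout of a synthetic classifier training set."""

    n_maps: int = 20
    placements_per_map: int = 100
    correct_fraction: float = 0.2
    #: class-separation control: sd of per-feature independent noise in
    #: units of the class gap.  0 -> each feature separates alone.
    feature_overlap: float = 0.5
    seed: int = 1

    def __post_init__(self) -> None:
        if not 0.0 < self.correct_fraction < 1.0:
            raise ValueError("correct_fraction must lie in (0, 1)")


def _confined_walk(n: int, radius: float, rng: np.random.Generator,
                   max_tries: int = 200) -> np.ndarray:
    """Self-avoiding random walk of ``n`` points inside a sphere."""
    pts = [np.zeros(3)]
    while len(pts) < n:
        prev = pts[-1]
        placed = False
        min_sep = MIN_SEPARATION
        for attempt in range(max_tries):
            if attempt and attempt % 50 == 0:
                min_sep *= 0.8  # relax gradually rather than fail
            v = rng.normal(size=3)
            cand = prev + CA_STEP * v / np.linalg.norm(v)
            if np.linalg.norm(cand) > radius:
                continue
            if len(pts) > 1:
                d = np.linalg.norm(np.array(pts[:-1]) - cand, axis=1)
                if d.min() < min_sep:
                    continue
            pts.append(cand)
            placed = True
            break
        if not placed:
            raise ValueError(
                f"cannot grow a {n}-residue domain in radius {radius:.1f} A")
    return np.array(pts)


def _make_residue(number: int, ca: np.ndarray, plddt: float) -> Residue:
    atoms = [Atom("CA", "C", ca.copy(), plddt)]
    for name, off in _DUMMY_ATOMS.items():
        atoms.append(Atom(name, name[0], ca + off, plddt))
    return Residue(number, "", "ALA", atoms, plddt)


def make_planted_model(spec: PlantedModelSpec
                       ) -> tuple[PredictedModel, dict, PAEMatrix]:
    """Synthetic multi-domain model with planted labels and block PAE.

    Returns the model (single chain A, residues numbered from 1), a map of
    residue key -> planted domain index (1-based; linker residues carry
    the index of the sequence-nearer domain), and a block-structured PAE
    (low within domains, high between, intermediate for linker rows).
    """
    rng = np.random.default_rng(spec.seed)
    (core_mu, core_sd), (link_mu, link_sd) = spec.confidence_profile
    centroids = [np.array([i * spec.inter_centroid_separation, 0.0, 0.0])
                 for i in range(spec.n_domains)]
    residues: list[Residue] = []
    domain_of: list[int] = []       # per residue, 1-based; 0 for linker
    number = 0
    last_point: np.ndarray | None = None
    for dom, (n_res, centre) in enumerate(zip(spec.residues_per_domain,
                                              centroids), start=1):
        radius = 2.5 * n_res ** (1.0 / 3.0)
        walk = _confined_walk(n_res, radius, rng) + centre
        if last_point is not None and spec.linker_length > 0:
            # extended linker between the previous end and this start
            start, end = last_point, walk[0]
            for j in range(1, spec.linker_length + 1):
                frac = j / (spec.linker_length + 1)
                pos = start + frac * (end - start)
                pos = pos + rng.normal(scale=0.3, size=3)
                number += 1
                plddt = float(np.clip(rng.normal(link_mu, link_sd), 0, 100))
                residues.append(_make_residue(number, pos, plddt))
                domain_of.append(0)
        for pos in walk:
            number += 1
            plddt = float(np.clip(rng.normal(core_mu, core_sd), 0, 100))
            residues.append(_make_residue(number, pos, plddt))
            domain_of.append(dom)
        last_point = walk[-1]

    # attach linker residues to the sequence-nearer domain for labelling
    labels_arr = np.array(domain_of)
    idx = np.arange(len(labels_arr))
    for i in idx[labels_arr == 0]:
        before = labels_arr[:i][labels_arr[:i] > 0]
        after = labels_arr[i:][labels_arr[i:] > 0]
        d_before = i - idx[:i][labels_arr[:i] > 0].max() if before.size else np.inf
        d_after = idx[i:][labels_arr[i:] > 0].min() - i if after.size else np.inf
        labels_arr[i] = before[-1] if d_before <= d_after else after[0]

    model = PredictedModel("planted", [Chain("A", residues)], ScoreType.PLDDT)
    keys = model.residue_keys()
    labels = {k: int(lab) for k, lab in zip(keys, labels_arr)}

    n = len(residues)
    dom_arr = np.array(domain_of)
    pae = np.empty((n, n))
    same = (dom_arr[:, None] == dom_arr[None, :]) & (dom_arr[:, None] > 0)
    linker = (dom_arr[:, None] == 0) | (dom_arr[None, :] == 0)
    pae[:] = rng.normal(*_PAE_INTER, size=(n, n))
    pae[linker] = rng.normal(*_PAE_LINKER, size=(n, n))[linker]
    pae[same] = rng.normal(*_PAE_INTRA, size=(n, n))[same]
    np.fill_diagonal(pae, 0.3)
    pae = np.clip(pae, 0.2, None)
    return model, labels, PAEMatrix(pae, keys)


def make_target_map(models_with_poses: Sequence[tuple[PredictedModel, Placement]],
                    voxel: float = 2.0, resolution: float = 6.0,
                    noise_sd: float = 0.0, seed: int = 0,
                    padding: float = 8.0) -> DensityMap:
    """Render the union of posed models into one map, plus optional noise.

    Grid bounds cover all placed atoms + padding; ``noise_sd`` is the SD of
    added white Gaussian voxel noise in absolute density units.  With a
    single model and zero noise, the result equals the simulated density
    of the posed model on the same grid.
    """
    if not models_with_poses:
        raise ValueError("at least one posed model is required")
    placed = [pose.place(model) for model, pose in models_with_poses]
    coords = np.vstack([m.atom_coordinates() for m in placed])
    lo = coords.min(axis=0) - padding
    hi = coords.max(axis=0) + padding
    shape = np.maximum(np.ceil((hi - lo) / voxel).astype(int) + 1, 4)
    template = DensityMap(np.zeros(shape, dtype=np.float32),
                          np.full(3, float(voxel)), lo, resolution)
    acc = np.zeros(shape, dtype=np.float64)
    for m in placed:
        acc += simulate_on_grid(m, template, resolution).grid
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        acc += rng.normal(scale=noise_sd, size=shape)
    return DensityMap(acc.astype(np.float32), template.voxel_size,
                      template.origin, resolution)


def make_classifier_fixture(spec: ClassifierFixtureSpec) -> TrainingSet:
    """Synthetic score rows with map groups and controlled separability.

    Each row carries a latent placement quality (high for correct
    placements, low for incorrect, plus a small per-map offset); every
    feature is its class baseline plus the class gap times
    (latent + feature_overlap * independent noise), clipped to the score's
    valid range.  With the default overlap no single feature separates the
    classes fully, while the joint feature set does — the construction the
    ablation study probes.
    """
    rng = np.random.default_rng(spec.seed)
    rows: list[TrainingRow] = []
    for m in range(spec.n_maps):
        group = f"map{m:03d}"
        resolution = float(rng.uniform(3.0, 10.0))
        map_offset = rng.normal(scale=0.05)
        n_correct = int(round(spec.correct_fraction * spec.placements_per_map))
        labels = np.zeros(spec.placements_per_map, dtype=int)
        labels[:n_correct] = 1
        for label in labels:
            latent = rng.normal(loc=float(label), scale=0.2) + map_offset
            values = {}
            for name, (mu0, mu1) in FIXTURE_FEATURE_MEANS.items():
                gap = mu1 - mu0
                noise = rng.normal(scale=spec.feature_overlap)
                raw = mu0 + gap * (latent + noise)
                values[name] = float(np.clip(raw, *_FEATURE_CLIP[name]))
            rows.append(TrainingRow(
                ScoreVector(**values, resolution=resolution),
                int(label), group))
    return TrainingSet(rows)
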