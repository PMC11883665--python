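"""Density maps, model-to-map simulation, and map-model fit scores.

A :class:`DensityMap` is a 3-D voxel grid with an origin, voxel size and a
nominal resolution, stored in MRC/CCP4 2014 files (gemmi backend).  Model
density is simulated by placing an isotropic Gaussian of width
sigma = resolution / (pi * sqrt(2)) at each atom, normalised to unit total
weight per atom.

The fit scores are the features the placement classifier consumes:

* **CC** — Pearson cross-correlation of two maps over (optionally masked)
  voxels.
* **MI** — mutual information (nats) of the joint voxel-intensity
  histogram.
* **FSCavg** — the unweighted mean of Fourier shell correlations over
  spherical shells one Fourier voxel wide, up to 1/resolution (or
  Nyquist).
* **SMOC** — segment-based Manders' overlap coefficient: for each residue,
  the Manders coefficient between the experimental map and the simulated
  whole-model map over the footprint of a sliding sequence window.
* **overlap_map / overlap_model** — the fraction of the map footprint
  covered by the model footprint and vice versa, after thresholding each
  map at a multiple of its own standard deviation; these tell the
  classifier about the relative sizes of map and model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np

from .structures import PredictedModel

logger = logging.getLogger(__name__)

__all__ = [
    "DensityMap",
    "ScoreVector",
    "GeometryError",
    "read_map",
    "write_map",
    "simulate_map",
    "simulate_on_grid",
    "cross_correlation",
    "mutual_information",
    "fsc_average",
    "smoc",
    "overlap_scores",
    "feature_vector",
]

#: Gaussian kernels are rasterised out to this many sigmas.
_KERNEL_CUTOFF_SIGMA = 4.0


class GeometryError(ValueError):
    """Two maps do not share grid geometry, or a grid parameter is invalid."""


class FormatError(ValueError):
    """Not a readable MRC/CCP4 map."""


@dataclass
class DensityMap:
    """3-D density grid: ``grid[i, j, k]`` sits at origin + (i,j,k)*voxel."""

    grid: np.ndarray
    voxel_size: np.ndarray            # (3,) Angstrom
    origin: np.ndarray                # (3,) Angstrom
    nominal_resolution: float | None = None

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=np.float32)
        self.voxel_size = np.asarray(self.voxel_size, dtype=float).reshape(3)
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        if self.grid.ndim != 3:
            raise GeometryError(f"grid must be 3-D, got shape {self.grid.shape}")
        if not np.all(np.isfinite(self.grid)):
            raise GeometryError("grid contains non-finite values")
        if np.any(self.voxel_size <= 0):
            raise GeometryError(f"voxel size must be positive: {self.voxel_size}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.grid.shape

    def same_geometry(self, other: "DensityMap", tol: float = 1e-4) -> bool:
        return (self.shape == other.shape
                and np.allclose(self.voxel_size, other.voxel_size, atol=tol)
                and np.allclose(self.origin, other.origin, atol=tol))

    def copy(self) -> "DensityMap":
        return DensityMap(self.grid.copy(), self.voxel_size.copy(),
                          self.origin.copy(), self.nominal_resolution)

    def empty_like(self) -> "DensityMap":
        return DensityMap(np.zeros(self.shape, dtype=np.float32),
                          self.voxel_size.copy(), self.origin.copy(),
                          self.nominal_resolution)


def read_map(path: str | Path,
             nominal_resolution: float | None = None) -> DensityMap:
    """Read an MRC/CCP4 2014 map; float32 grids round-trip bit-faithfully."""
    path = Path(path)
    try:
        ccp4 = gemmi.read_ccp4_map(str(path))
    except (RuntimeError, ValueError, OSError) as exc:
        raise FormatError(f"cannot read MRC/CCP4 map {path}: {exc}") from exc
    grid = np.array(ccp4.grid, copy=True)
    voxel = np.array(ccp4.grid.spacing, dtype=float)
    origin = np.array([ccp4.header_float(w) for w in (50, 51, 52)], dtype=float)
    if np.allclose(origin, 0.0):
        # fall back to the NXSTART-style start words
        start = np.array([ccp4.header_i32(w) for w in (5, 6, 7)], dtype=float)
        origin = start * voxel
    return DensityMap(grid, voxel, origin, nominal_resolution)


def write_map(dmap: DensityMap, path: str | Path) -> Path:
    """Write an MRC/CCP4 2014 map (origin stored in the ORIGIN words)."""
    path = Path(path)
    grid = gemmi.FloatGrid(np.ascontiguousarray(dmap.grid, dtype=np.float32))
    nx, ny, nz = dmap.shape
    vx, vy, vz = dmap.voxel_size
    grid.unit_cell = gemmi.UnitCell(nx * vx, ny * vy, nz * vz, 90, 90, 90)
    ccp4 = gemmi.Ccp4Map()
    ccp4.grid = grid
    ccp4.update_ccp4_header()
    for w, v in zip((50, 51, 52), dmap.origin):
        ccp4.set_header_float(w, float(v))
    try:
        ccp4.write_ccp4_map(str(path))
    except (OSError, RuntimeError) as exc:
        raise OSError(f"cannot write map to {path}: {exc}") from exc
    return path


# ---------------------------------------------------------------------------
# simulation

def _gaussian_sigma(resolution: float) -> float:
    return resolution / (np.pi * np.sqrt(2.0))


def _splat_atoms(grid: np.ndarray, coords: np.ndarray, origin: np.ndarray,
                 voxel: np.ndarray, sigma: float) -> None:
    """Add a unit-weight Gaussian per atom, in place.

    Kernel patches are normalised against the *unclipped* patch sum, so
    interior density is exactly translation-covariant under whole-voxel
    shifts of the model.
    """
    half = np.ceil(_KERNEL_CUTOFF_SIGMA * sigma / voxel).astype(int)
    shape = np.array(grid.shape)
    axes_rel = [np.arange(-h, h + 1) * v for h, v in zip(half, voxel)]
    for pos in coords:
        frac = (pos - origin) / voxel
        centre = np.round(frac).astype(int)
        offset = (frac - centre) * voxel  # sub-voxel remainder
        dx2 = np.square(axes_rel[0] - offset[0])
        dy2 = np.square(axes_rel[1] - offset[1])
        dz2 = np.square(axes_rel[2] - offset[2])
        d2 = dx2[:, None, None] + dy2[None, :, None] + dz2[None, None, :]
        kernel = np.exp(-d2 / (2.0 * sigma * sigma))
        total = kernel.sum()
        if total <= 0:
            continue
        kernel /= total
        lo = centre - half
        hi = centre + half + 1
        glo = np.clip(lo, 0, shape)
        ghi = np.clip(hi, 0, shape)
        if np.any(glo >= ghi):
            continue
        klo = glo - lo
        khi = np.array(kernel.shape) - (hi - ghi)
        grid[glo[0]:ghi[0], glo[1]:ghi[1], glo[2]:ghi[2]] += kernel[
            klo[0]:khi[0], klo[1]:khi[1], klo[2]:khi[2]]


def simulate_on_grid(model: PredictedModel, template: DensityMap,
                     resolution: float | None = None) -> DensityMap:
    """Simulate model density on an existing grid geometry.

    Atoms outside the grid contribute only their in-grid kernel tails.
    Linear in the atom set: simulating two halves separately and summing
    equals simulating the union.
    """
    res = resolution or template.nominal_resolution
    if res is None:
        raise GeometryError("a resolution is required to simulate density")
    _check_resolution(res, template.voxel_size)
    out = template.empty_like()
    out.nominal_resolution = res
    grid = out.grid.astype(np.float64)
    _splat_atoms(grid, model.atom_coordinates(), out.origin,
                 out.voxel_size, _gaussian_sigma(res))
    out.grid = grid.astype(np.float32)
    return out


def _check_resolution(resolution: float, voxel: np.ndarray) -> None:
    if resolution < 2.0 * float(np.max(voxel)):
        raise GeometryError(
            f"resolution {resolution} A is below the Nyquist limit "
            f"2*voxel = {2 * float(np.max(voxel))} A")


def simulate_map(model: PredictedModel, voxel_size: float,
                 resolution: float, padding: float = 5.0) -> DensityMap:
    """Simulate model density on a fresh grid covering the model + padding.

    Each atom contributes an isotropic Gaussian of width
    sigma = resolution/(pi*sqrt(2)) with unit total weight, so the grid sum
    approximates the atom count.
    """
    if model.n_atoms == 0:
        raise GeometryError("cannot simulate density for an empty model")
    voxel = np.full(3, float(voxel_size))
    _check_resolution(resolution, voxel)
    coords = model.atom_coordinates()
    lo = coords.min(axis=0) - padding
    hi = coords.max(axis=0) + padding
    shape = np.maximum(np.ceil((hi - lo) / voxel).astype(int) + 1, 4)
    template = DensityMap(np.zeros(shape, dtype=np.float32), voxel, lo,
                          resolution)
    return simulate_on_grid(model, template, resolution)


# ---------------------------------------------------------------------------
# scores

def _check_same_geometry(a: DensityMap, b: DensityMap) -> None:
    if not a.same_geometry(b):
        raise GeometryError(
            f"maps differ in geometry: {a.shape}/{a.voxel_size} vs "
            f"{b.shape}/{b.voxel_size}; resample first")


def resample_like(src: DensityMap, template: DensityMap) -> DensityMap:
    """Trilinearly interpolate ``src`` onto ``template``'s grid."""
    from scipy.ndimage import map_coordinates
    idx = np.indices(template.shape, dtype=float)
    pos = template.origin[:, None, None, None] + \
        idx * template.voxel_size[:, None, None, None]
    src_idx = (pos - src.origin[:, None, None, None]) / \
        src.voxel_size[:, None, None, None]
    grid = map_coordinates(src.grid.astype(float), src_idx, order=1,
                           mode="constant", cval=0.0)
    return DensityMap(grid, template.voxel_size.copy(),
                      template.origin.copy(), src.nominal_resolution)


def cross_correlation(a: DensityMap, b: DensityMap,
                      mask: np.ndarray | None = None) -> float:
    """Pearson correlation of voxel intensities over (masked) voxels."""
    _check_same_geometry(a, b)
    x = a.grid.astype(np.float64).ravel()
    y = b.grid.astype(np.float64).ravel()
    if mask is not None:
        m = np.asarray(mask, dtype=bool).ravel()
        if m.shape != x.shape:
            raise GeometryError("mask shape does not match grid")
        x, y = x[m], y[m]
    if x.size < 2:
        raise GeometryError("too few voxels to correlate")
    x = x - x.mean()
    y = y - y.mean()
    denom = np.sqrt((x @ x) * (y @ y))
    if denom == 0:
        raise ValueError("cross-correlation undefined for zero-variance input")
    return float((x @ y) / denom)


def mutual_information(a: DensityMap, b: DensityMap, bins: int = 20) -> float:
    """Mutual information (nats) of the joint voxel-intensity histogram."""
    _check_same_geometry(a, b)
    x = a.grid.ravel()
    y = b.grid.ravel()
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        logger.info("mutual information of a constant map is 0 by convention")
        return 0.0
    joint, _, _ = np.histogram2d(x, y, bins=bins)
    pxy = joint / joint.sum()
    px = pxy.sum(axis=1, keepdims=True)
    py = pxy.sum(axis=0, keepdims=True)
    nz = pxy > 0
    return float(np.sum(pxy[nz] * np.log(pxy[nz] / (px @ py)[nz])))


def fsc_average(a: DensityMap, b: DensityMap,
                max_frequency: float | None = None) -> float:
    """Mean Fourier shell correlation over shells one Fourier voxel wide.

    Shells run from the first non-DC shell up to ``max_frequency`` (1/A;
    default 1/nominal_resolution of either map, else Nyquist).  Non-cubic
    grids are zero-padded to a cube; voxels must be isotropic.
    """
    _check_same_geometry(a, b)
    if len(set(np.round(a.voxel_size, 6))) != 1:
        raise GeometryError("FSC requires isotropic voxels")
    n = max(a.shape)
    voxel = float(a.voxel_size[0])
    ga = np.zeros((n, n, n))
    gb = np.zeros((n, n, n))
    sx, sy, sz = a.shape
    ga[:sx, :sy, :sz] = a.grid
    gb[:sx, :sy, :sz] = b.grid
    fa = np.fft.fftn(ga)
    fb = np.fft.fftn(gb)
    freq_idx = np.fft.fftfreq(n) * n
    r = np.sqrt(freq_idx[:, None, None] ** 2 + freq_idx[None, :, None] ** 2
                + freq_idx[None, None, :] ** 2)
    shell = np.rint(r).astype(int)
    if max_frequency is None:
        res = a.nominal_resolution or b.nominal_resolution
        max_frequency = (1.0 / res) if res else 1.0 / (2.0 * voxel)
    r_max = min(int(np.floor(max_frequency * n * voxel)), n // 2)
    if r_max < 1:
        raise GeometryError("frequency limit excludes every shell")
    num = np.real(fa * np.conj(fb))
    pa = np.abs(fa) ** 2
    pb = np.abs(fb) ** 2
    fscs = []
    flat_shell = shell.ravel()
    num_s = np.bincount(flat_shell, weights=num.ravel())
    pa_s = np.bincount(flat_shell, weights=pa.ravel())
    pb_s = np.bincount(flat_shell, weights=pb.ravel())
    for s in range(1, r_max + 1):
        denom = np.sqrt(pa_s[s] * pb_s[s])
        fscs.append(num_s[s] / denom if denom > 0 else 0.0)
    return float(np.mean(fscs))


def _footprint_mask(coords: np.ndarray, template: DensityMap,
                    radius: float) -> np.ndarray:
    """Boolean grid of voxels within ``radius`` of any of ``coords``."""
    mask = np.zeros(template.shape, dtype=bool)
    voxel = template.voxel_size
    half = np.ceil(radius / voxel).astype(int)
    shape = np.array(template.shape)
    axes = [np.arange(-h, h + 1) * v for h, v in zip(half, voxel)]
    ball = (axes[0][:, None, None] ** 2 + axes[1][None, :, None] ** 2
            + axes[2][None, None, :] ** 2) <= radius ** 2
    for pos in coords:
        centre = np.round((pos - template.origin) / voxel).astype(int)
        lo = centre - half
        hi = centre + half + 1
        glo = np.clip(lo, 0, shape)
        ghi = np.clip(hi, 0, shape)
        if np.any(glo >= ghi):
            continue
        klo = glo - lo
        khi = np.array(ball.shape) - (hi - ghi)
        mask[glo[0]:ghi[0], glo[1]:ghi[1], glo[2]:ghi[2]] |= ball[
            klo[0]:khi[0], klo[1]:khi[1], klo[2]:khi[2]]
    return mask


def smoc(model: PredictedModel, dmap: DensityMap, window: int = 9,
         resolution: float | None = None,
         footprint_radius: float | None = None,
         ) -> tuple[dict, float]:
    """Per-residue segment-based Manders' overlap coefficient and its mean.

    The whole model is simulated once on the map grid; each residue is
    scored by the Manders coefficient sum(x*y)/sqrt(sum(x^2)*sum(y^2))
    between the simulated and experimental map over the footprint of the
    ``window``-residue sequence window centred on it (truncated at chain
    ends).  A residue whose window footprint is empty scores 0 (logged).
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    res = resolution or dmap.nominal_resolution or 3.0 * float(dmap.voxel_size.max())
    sim = simulate_on_grid(model, dmap, res)
    radius = footprint_radius or max(2.5, 2.0 * _gaussian_sigma(res))
    x = sim.grid.astype(np.float64)
    y = dmap.grid.astype(np.float64)
    half = window // 2
    scores: dict = {}
    for chain in model.chains:
        n = len(chain.residues)
        for i, resi in enumerate(chain.residues):
            lo, hi = max(0, i - half), min(n, i + half + 1)
            coords = np.array([a.xyz for r in chain.residues[lo:hi]
                               for a in r.atoms])
            mask = _footprint_mask(coords, dmap, radius)
            key = (chain.chain_id, resi.number, resi.insertion_code)
            if not mask.any():
                logger.info("SMOC: empty footprint for residue %s", key)
                scores[key] = 0.0
                continue
            xs, ys = x[mask], y[mask]
            denom = np.sqrt((xs @ xs) * (ys @ ys))
            scores[key] = float((xs @ ys) / denom) if denom > 0 else 0.0
    return scores, float(np.mean(list(scores.values())))


def overlap_scores(model: PredictedModel, dmap: DensityMap,
                   level: float = 1.0,
                   resolution: float | None = None) -> tuple[float, float]:
    """Relative-size overlap scores of the model vs the map footprint.

    Both the experimental map and the model-simulated map are thresholded
    at ``level`` times their own standard deviation.  ``overlap_model`` is
    the fraction of model-footprint voxels inside the map footprint, and
    ``overlap_map`` the converse; both lie in [0, 1].
    """
    res = resolution or dmap.nominal_resolution or 3.0 * float(dmap.voxel_size.max())
    sim = simulate_on_grid(model, dmap, res)
    map_fp = dmap.grid > level * dmap.grid.std()
    model_fp = sim.grid > level * sim.grid.std()
    if not map_fp.any() or not model_fp.any():
        logger.info("overlap scores: empty footprint(s); returning (0, 0)")
        return 0.0, 0.0
    inter = np.count_nonzero(map_fp & model_fp)
    overlap_map = inter / np.count_nonzero(map_fp)
    overlap_model = inter / np.count_nonzero(model_fp)
    return float(overlap_map), float(overlap_model)


@dataclass
class ScoreVector:
    """The map-model features consumed by the placement classifier.

    Field order is fixed; ``resolution`` is carried along but excluded from
    classification by default.
    """

    fsc_avg: float
    mi: float
    cc: float
    smoc: float
    overlap_map: float
    overlap_model: float
    resolution: float = field(default=float("nan"))

    FEATURES = ("fsc_avg", "mi", "cc", "smoc", "overlap_map", "overlap_model")

    def as_array(self, use_resolution: bool = False) -> np.ndarray:
        vals = [getattr(self, f) for f in self.FEATURES]
        if use_resolution:
            vals.append(self.resolution)
        return np.array(vals, dtype=float)

    @classmethod
    def feature_names(cls, use_resolution: bool = False) -> list[str]:
        names = list(cls.FEATURES)
        if use_resolution:
            names.append("resolution")
        return names

    def to_dict(self) -> dict:
        return {f: getattr(self, f) for f in (*self.FEATURES, "resolution")}


def _crop_to_model(model: PredictedModel, maps: list[DensityMap],
                   margin: float) -> list[DensityMap]:
    """Crop maps to the model's bounding box + margin (same region each)."""
    coords = model.atom_coordinates()
    ref = maps[0]
    lo = np.floor((coords.min(axis=0) - margin - ref.origin)
                  / ref.voxel_size).astype(int)
    hi = np.ceil((coords.max(axis=0) + margin - ref.origin)
                 / ref.voxel_size).astype(int) + 1
    lo = np.clip(lo, 0, np.array(ref.shape) - 1)
    hi = np.clip(hi, lo + 2, ref.shape)
    out = []
    for m in maps:
        sub = m.grid[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
        out.append(DensityMap(sub, m.voxel_size.copy(),
                              m.origin + lo * m.voxel_size,
                              m.nominal_resolution))
    return out


def feature_vector(model: PredictedModel, dmap: DensityMap,
                   resolution: float | None = None,
                   mi_bins: int = 20, smoc_window: int = 9) -> ScoreVector:
    """Assemble all six fit scores (plus resolution) for a placed model.

    CC, MI and FSCavg are evaluated over the placed model's neighbourhood
    (its bounding box plus a kernel-width margin), so a correctly placed
    slice of a larger assembly still scores near 1; the overlap scores
    retain the global map footprint and carry the relative-size signal.
    A locally flat experimental region (placement far outside the density)
    yields CC 0 by convention, logged.
    """
    res = resolution or dmap.nominal_resolution
    sim = simulate_on_grid(model, dmap, res)
    margin = 2.0 * _gaussian_sigma(res or 3.0 * float(dmap.voxel_size.max()))
    sim_c, map_c = _crop_to_model(model, [sim, dmap], margin)
    try:
        cc = cross_correlation(sim_c, map_c)
    except ValueError:
        logger.info("flat local region: CC set to 0")
        cc = 0.0
    mi = mutual_information(sim_c, map_c, bins=mi_bins)
    fsc = fsc_average(sim_c, map_c)
    _, smoc_mean = smoc(model, dmap, window=smoc_window, resolution=res)
    omap, omodel = overlap_scores(model, dmap, resolution=res)
    return ScoreVector(fsc_avg=fsc, mi=mi, cc=cc, smoc=smoc_mean,
                       overlap_map=omap, overlap_model=omodel,
                       resolution=res if res is not None else float("nan"))
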