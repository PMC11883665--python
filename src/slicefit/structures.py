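"""Atomic-model and PAE containers plus PDB/mmCIF/JSON I/O.

Predicted protein models carry a per-residue confidence score in the
B-factor column: pLDDT (0-100) for AlphaFold2-style predictors, fractional
pLDDT (0-1) for ESMFold, or an estimated positional error in Angstrom for
RoseTTAFold-style output.  This module reads such files (via gemmi), keeps
the declared score type alongside the coordinates, and exposes the Calpha
coordinate table that the slicing and fitting stages consume.  The
predicted aligned error (PAE) matrix, when available, is read from the two
common JSON dialects (AlphaFold-DB ``predicted_aligned_error`` and
ColabFold ``pae``).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterator, NamedTuple, Sequence

import gemmi
import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "ScoreType",
    "Atom",
    "Residue",
    "Chain",
    "PredictedModel",
    "PAEMatrix",
    "CaTable",
    "ResidueKey",
    "read_model",
    "write_model",
    "read_pae",
    "ca_coordinates",
]

#: (chain id, residue number, insertion code) — unique per residue.
ResidueKey = tuple[str, int, str]


class ScoreType(str, Enum):
    """Interpretation of the B-factor column of a predicted model."""

    PLDDT = "plddt"                      # 0-100
    PLDDT_FRACTIONAL = "plddt_fractional"  # 0-1
    RMSD_EST = "rmsd_est"                # estimated error, Angstrom, >= 0
    PSEUDO_B = "pseudo_b"                # Angstrom^2, >= 0

    @property
    def valid_range(self) -> tuple[float, float]:
        return {
            ScoreType.PLDDT: (0.0, 100.0),
            ScoreType.PLDDT_FRACTIONAL: (0.0, 1.0),
            ScoreType.RMSD_EST: (0.0, np.inf),
            ScoreType.PSEUDO_B: (0.0, np.inf),
        }[self]


class ModelInputError(ValueError):
    """Unreadable, empty or malformed model/PAE input."""


class ValidationError(ValueError):
    """Input read correctly but violates a declared contract."""


@dataclass
class Atom:
    name: str
    element: str
    xyz: np.ndarray  # shape (3,), Angstrom
    b_iso: float

    def __post_init__(self) -> None:
        self.xyz = np.asarray(self.xyz, dtype=float)
        if self.xyz.shape != (3,) or not np.all(np.isfinite(self.xyz)):
            raise ValidationError(f"atom {self.name}: non-finite coordinates")


@dataclass
class Residue:
    number: int
    insertion_code: str
    name: str
    atoms: list[Atom]
    confidence: float

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def ca(self) -> Atom | None:
        return self.atom("CA")


@dataclass
class Chain:
    chain_id: str
    residues: list[Residue] = field(default_factory=list)


@dataclass
class PredictedModel:
    """A predicted protein model with a declared confidence score type."""

    model_id: str
    chains: list[Chain]
    score_type: ScoreType = ScoreType.PLDDT

    def iter_residues(self) -> Iterator[tuple[str, Residue]]:
        for chain in self.chains:
            for res in chain.residues:
                yield chain.chain_id, res

    def residue_keys(self) -> list[ResidueKey]:
        return [(cid, r.number, r.insertion_code) for cid, r in self.iter_residues()]

    @property
    def n_residues(self) -> int:
        return sum(len(c.residues) for c in self.chains)

    @property
    def n_atoms(self) -> int:
        return sum(len(r.atoms) for _, r in self.iter_residues())

    def atom_coordinates(self) -> np.ndarray:
        """All atom positions as an (n_atoms, 3) array in file order."""
        coords = [a.xyz for _, r in self.iter_residues() for a in r.atoms]
        return np.array(coords, dtype=float).reshape(-1, 3)

    def select(self, keys: Sequence[ResidueKey], model_id: str | None = None) -> "PredictedModel":
        """Sub-model restricted to ``keys``, preserving chain/file order."""
        wanted = set(keys)
        chains: list[Chain] = []
        for chain in self.chains:
            kept = [r for r in chain.residues
                    if (chain.chain_id, r.number, r.insertion_code) in wanted]
            if kept:
                chains.append(Chain(chain.chain_id, [_copy_residue(r) for r in kept]))
        return PredictedModel(model_id or self.model_id, chains, self.score_type)

    def copy(self) -> "PredictedModel":
        return self.select(self.residue_keys())

    def validate(self) -> None:
        keys = self.residue_keys()
        if len(keys) != len(set(keys)):
            dupes = sorted({k for k in keys if keys.count(k) > 1})
            raise ValidationError(f"duplicate residue keys: {dupes[:5]}")
        lo, hi = self.score_type.valid_range
        bad = [(cid, r.number) for cid, r in self.iter_residues()
               if not (lo <= r.confidence <= hi)]
        if bad:
            raise ValidationError(
                f"{len(bad)} residue confidence values outside "
                f"[{lo}, {hi}] for score type {self.score_type.value}: "
                f"first offenders {bad[:5]}")


def _copy_residue(r: Residue) -> Residue:
    return Residue(r.number, r.insertion_code, r.name,
                   [Atom(a.name, a.element, a.xyz.copy(), a.b_iso) for a in r.atoms],
                   r.confidence)


@dataclass
class PAEMatrix:
    """n x n predicted aligned error (Angstrom), aligned to model residues.

    ``values[i, j]`` is the expected error at residue i when the prediction
    and the truth are superposed on residue j; it need not be symmetric.
    """

    values: np.ndarray
    residue_keys: list[ResidueKey]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.residue_keys)
        if self.values.shape != (n, n):
            raise ValidationError(
                f"PAE shape {self.values.shape} does not match {n} residue keys")
        if np.any(self.values < 0):
            raise ValidationError("PAE contains negative entries")

    @property
    def n(self) -> int:
        return len(self.residue_keys)

    def subset(self, keys: Sequence[ResidueKey]) -> "PAEMatrix":
        """Re-index to ``keys`` (e.g. after trimming low-confidence residues)."""
        index = {k: i for i, k in enumerate(self.residue_keys)}
        missing = [k for k in keys if k not in index]
        if missing:
            raise ValidationError(f"keys absent from PAE: {missing[:5]}")
        idx = np.array([index[k] for k in keys])
        return PAEMatrix(self.values[np.ix_(idx, idx)], list(keys))


class CaTable(NamedTuple):
    """Ordered Calpha coordinate table (one row per Calpha-bearing residue)."""

    keys: list[ResidueKey]
    coords: np.ndarray          # (n, 3)
    omitted: list[ResidueKey]   # residues lacking a Calpha atom


# ---------------------------------------------------------------------------
# I/O

def _sniff_format(path: Path) -> gemmi.CoorFormat:
    """Detect PDB vs mmCIF from content, not extension."""
    head = path.read_text(errors="replace")[:4096]
    stripped = head.lstrip()
    if stripped.startswith("data_") or "_atom_site." in head or stripped.startswith("#"):
        return gemmi.CoorFormat.Mmcif
    return gemmi.CoorFormat.Pdb


def read_model(path: str | Path,
               score_type: ScoreType | str = ScoreType.PLDDT,
               override_b_column: bool = False) -> PredictedModel:
    """Read a PDB or mmCIF model, interpreting B values per ``score_type``.

    Non-polymer entities (waters, ligands) are dropped with a logged count.
    Residue confidence is taken from the Calpha atom's B value (other atoms'
    values are preserved but not used for scoring).  With
    ``override_b_column`` the range validation of the declared score type is
    skipped.
    """
    path = Path(path)
    score_type = ScoreType(score_type)
    if not path.is_file() or path.stat().st_size == 0:
        raise ModelInputError(f"unreadable or empty model file: {path}")
    try:
        st = gemmi.read_structure(str(path), format=_sniff_format(path))
    except (RuntimeError, ValueError) as exc:
        raise ModelInputError(f"cannot parse {path}: {exc}") from exc
    st.setup_entities()
    n_before = sum(len(ch) for ch in st[0])
    st.remove_ligands_and_waters()
    st.remove_empty_chains()
    n_dropped = n_before - sum(len(ch) for ch in st[0])
    if n_dropped:
        logger.info("dropped %d non-polymer residues from %s", n_dropped, path.name)
    if len(st) == 0 or sum(len(ch) for ch in st[0]) == 0:
        raise ModelInputError(f"no protein residues in {path}")

    chains: list[Chain] = []
    for gch in st[0]:
        residues = []
        for gres in gch:
            atoms = [Atom(a.name, a.element.name,
                          np.array([a.pos.x, a.pos.y, a.pos.z]), a.b_iso)
                     for a in gres]
            if not atoms:
                continue
            ca = next((a for a in atoms if a.name == "CA"), None)
            conf = float(ca.b_iso if ca is not None else atoms[0].b_iso)
            icode = gres.seqid.icode.strip()
            residues.append(Residue(gres.seqid.num, icode, gres.name, atoms, conf))
        if residues:
            chains.append(Chain(gch.name, residues))

    model = PredictedModel(path.stem, chains, score_type)
    if not override_b_column:
        model.validate()
    else:
        # still reject duplicate keys / non-finite coordinates
        keys = model.residue_keys()
        if len(keys) != len(set(keys)):
            raise ValidationError("duplicate residue keys")
    return model


def _to_gemmi(model: PredictedModel) -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = model.model_id
    gm = gemmi.Model("1")
    for chain in model.chains:
        gch = gemmi.Chain(chain.chain_id)
        for res in chain.residues:
            gres = gemmi.Residue()
            gres.name = res.name
            gres.seqid = gemmi.SeqId(res.number, res.insertion_code or " ")
            for atom in res.atoms:
                ga = gemmi.Atom()
                ga.name = atom.name
                ga.element = gemmi.Element(atom.element or "X")
                ga.pos = gemmi.Position(*atom.xyz)
                ga.b_iso = float(atom.b_iso)
                ga.occ = 1.0
                gres.add_atom(ga)
            gch.add_residue(gres)
        gm.add_chain(gch)
    st.add_model(gm)
    st.setup_entities()
    return st


def write_model(model: PredictedModel, path: str | Path) -> Path:
    """Write ``model`` as PDB, or mmCIF for a .cif/.mmcif extension.

    The B column holds each atom's current ``b_iso``.  Reading the file back
    reproduces residue keys, coordinates (to 1e-3 A) and B values (to 0.01).
    """
    path = Path(path)
    if model.n_residues == 0:
        raise ValidationError("refusing to write an empty model")
    st = _to_gemmi(model)
    try:
        if path.suffix.lower() in (".cif", ".mmcif"):
            st.make_mmcif_document().write_file(str(path))
        else:
            st.write_pdb(str(path))
    except (OSError, RuntimeError) as exc:
        raise OSError(f"cannot write model to {path}: {exc}") from exc
    return path


def read_pae(path: str | Path, model: PredictedModel) -> PAEMatrix:
    """Read a PAE JSON file in AlphaFold-DB or ColabFold dialect.

    The matrix must be n x n with n equal to the model's residue count; the
    dialect is auto-detected from the JSON keys.
    """
    path = Path(path)
    try:
        data = json.loads(path.read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise ModelInputError(f"cannot read PAE JSON {path}: {exc}") from exc
    if isinstance(data, list):
        if not data:
            raise ModelInputError(f"empty PAE JSON: {path}")
        data = data[0]
    if not isinstance(data, dict):
        raise ModelInputError(f"unrecognised PAE JSON structure in {path}")
    if "predicted_aligned_error" in data:
        values = np.asarray(data["predicted_aligned_error"], dtype=float)
    elif "pae" in data:
        values = np.asarray(data["pae"], dtype=float)
    else:
        raise ModelInputError(
            f"{path}: neither 'predicted_aligned_error' nor 'pae' key found")
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise ValidationError(f"PAE matrix is not square: shape {values.shape}")
    n = model.n_residues
    if values.shape[0] != n:
        raise ValidationError(
            f"PAE is {values.shape[0]}x{values.shape[0]} but model has {n} residues")
    return PAEMatrix(values, model.residue_keys())


def ca_coordinates(model: PredictedModel) -> CaTable:
    """Calpha coordinates in model order; residues lacking Calpha are reported.

    Raises on a model with zero Calpha atoms (nothing to cluster or fit).
    """
    keys: list[ResidueKey] = []
    coords: list[np.ndarray] = []
    omitted: list[ResidueKey] = []
    for cid, res in model.iter_residues():
        key = (cid, res.number, res.insertion_code)
        ca = res.ca
        if ca is None:
            omitted.append(key)
        else:
            keys.append(key)
            coords.append(ca.xyz)
    if not keys:
        raise ModelInputError(f"model {model.model_id} has no Calpha atoms")
    if omitted:
        logger.info("%s: %d residues lack a Calpha atom and were omitted",
                    model.model_id, len(omitted))
    return CaTable(keys, np.array(coords, dtype=float), omitted)
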