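"""Confidence-based truncation and pseudo-B-factor conversion.

Low-confidence residues rarely adopt the predicted conformation in an
experimental structure, so they are removed before a model is used for
placement: residues scoring below a pLDDT threshold (default 70, or 0.70
fractional) or above an estimated-error threshold (default 1.75 A) are
dropped whole.  The remaining per-residue scores are converted to pseudo-B
factors, the atomic displacement parameters likelihood-based placement
programs use to down-weight uncertain atoms.

The error-to-B conversion is B = (8*pi^2/3) * d^2 for an estimated
positional error d in Angstrom.  pLDDT is first mapped to an error estimate
with a monotone-decreasing map; the default is the exponential fit
d(p) = 1.5 * exp(4 * (0.7 - p/100)) widely used for processing predicted
models, and any strictly decreasing callable can be substituted.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Callable

from .structures import PredictedModel, ResidueKey, ScoreType, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_THRESHOLDS",
    "TrimReport",
    "EmptyResultError",
    "trim_by_confidence",
    "rmsd_to_bfactor",
    "plddt_to_rmsd",
    "plddt_to_bfactor",
    "apply_pseudo_b",
]

#: Default trim thresholds per score type (pseudo-B models use the pLDDT
#: default, converted).
DEFAULT_THRESHOLDS: dict[ScoreType, float] = {
    ScoreType.PLDDT: 70.0,
    ScoreType.PLDDT_FRACTIONAL: 0.70,
    ScoreType.RMSD_EST: 1.75,
    ScoreType.PSEUDO_B: 70.0,  # interpreted as pLDDT, converted before use
}

_EIGHT_PI2_3 = 8.0 * math.pi ** 2 / 3.0


class EmptyResultError(ValueError):
    """Every residue was removed; advise relaxing the threshold."""


@dataclass
class TrimReport:
    threshold_used: float
    threshold_units: ScoreType
    residues_removed: int
    residues_kept: int
    removed_keys: list[ResidueKey]

    def to_dict(self) -> dict:
        return {
            "threshold_used": self.threshold_used,
            "threshold_units": self.threshold_units.value,
            "residues_removed": self.residues_removed,
            "residues_kept": self.residues_kept,
            "removed_keys": [list(k) for k in self.removed_keys],
        }


def rmsd_to_bfactor(d: float) -> float:
    """Pseudo-B factor (A^2) for an estimated positional error ``d`` (A).

    B = (8*pi^2/3) * d^2; strictly increasing, 0 at d = 0.
    """
    if d < 0:
        raise ValueError(f"error estimate must be >= 0, got {d}")
    return _EIGHT_PI2_3 * d * d


def plddt_to_rmsd(plddt: float) -> float:
    """Default monotone-decreasing pLDDT (0-100) -> error estimate (A) map."""
    return 1.5 * math.exp(4.0 * (0.7 - plddt / 100.0))


def plddt_to_bfactor(plddt: float, fractional: bool = False,
                     error_map: Callable[[float], float] = plddt_to_rmsd) -> float:
    """Pseudo-B factor for a pLDDT score; strictly decreasing in pLDDT.

    Fractional scores (0-1) are rescaled by 100 first.  ``error_map`` is the
    pLDDT -> positional-error function; it must be strictly decreasing.
    """
    p = plddt * 100.0 if fractional else plddt
    if not 0.0 <= p <= 100.0:
        raise ValueError(f"pLDDT {plddt} outside valid range "
                         f"{'[0,1]' if fractional else '[0,100]'}")
    return rmsd_to_bfactor(error_map(p))


def _residue_pseudo_b(confidence: float, score_type: ScoreType,
                      error_map: Callable[[float], float]) -> float:
    if score_type is ScoreType.PLDDT:
        return plddt_to_bfactor(confidence, error_map=error_map)
    if score_type is ScoreType.PLDDT_FRACTIONAL:
        return plddt_to_bfactor(confidence, fractional=True, error_map=error_map)
    if score_type is ScoreType.RMSD_EST:
        return rmsd_to_bfactor(confidence)
    raise ValidationError(f"cannot convert score type {score_type.value}")


def trim_by_confidence(model: PredictedModel,
                       threshold: float | None = None,
                       error_map: Callable[[float], float] = plddt_to_rmsd,
                       ) -> tuple[PredictedModel, TrimReport]:
    """Remove whole residues whose confidence fails the threshold.

    For pLDDT-like scores, residues strictly below the threshold are
    removed; for error estimates, residues strictly above it.  For a model
    already carrying pseudo-B factors the threshold is given in pLDDT units,
    converted to a pseudo-B value, and residues strictly above that value
    are removed.  Boundary-equal residues are always kept.
    """
    st = model.score_type
    if threshold is None:
        threshold = DEFAULT_THRESHOLDS[st]
    lo, hi = st.valid_range
    if st is not ScoreType.PSEUDO_B and not (lo <= threshold <= hi):
        raise ValueError(
            f"threshold {threshold} outside valid range [{lo}, {hi}] "
            f"for score type {st.value}")

    if st in (ScoreType.PLDDT, ScoreType.PLDDT_FRACTIONAL):
        def remove(c: float) -> bool:
            return c < threshold
        units = st
        used = threshold
    elif st is ScoreType.RMSD_EST:
        def remove(c: float) -> bool:
            return c > threshold
        units = st
        used = threshold
    else:  # pseudo_b: threshold arrives in pLDDT units
        b_cut = plddt_to_bfactor(threshold, error_map=error_map)
        def remove(c: float) -> bool:
            return c > b_cut
        units = ScoreType.PSEUDO_B
        used = b_cut

    kept: list[ResidueKey] = []
    removed: list[ResidueKey] = []
    for cid, res in model.iter_residues():
        key = (cid, res.number, res.insertion_code)
        (removed if remove(res.confidence) else kept).append(key)
    if not kept:
        raise EmptyResultError(
            f"threshold {threshold} removed all {model.n_residues} residues "
            f"of {model.model_id}; relax the threshold")
    trimmed = model.select(kept)
    report = TrimReport(used, units, len(removed), len(kept), removed)
    logger.info("%s: trimmed %d/%d residues at %s threshold %g",
                model.model_id, report.residues_removed, model.n_residues,
                units.value, used)
    return trimmed, report


def apply_pseudo_b(model: PredictedModel,
                   error_map: Callable[[float], float] = plddt_to_rmsd,
                   ) -> PredictedModel:
    """Replace every atom's B value by the residue's pseudo-B factor.

    Coordinates are untouched; the returned model has score type
    ``pseudo_b``.  Applying to an already-converted model is a logged no-op.
    """
    if model.score_type is ScoreType.PSEUDO_B:
        logger.info("%s already carries pseudo-B factors; conversion skipped",
                    model.model_id)
        return model
    out = model.copy()
    out.score_type = ScoreType.PSEUDO_B
    for _, res in out.iter_residues():
        b = _residue_pseudo_b(res.confidence, model.score_type, error_map)
        res.confidence = b
        for atom in res.atoms:
            atom.b_iso = b
    return out
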