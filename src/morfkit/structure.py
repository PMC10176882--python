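"""Structure-model metrics: pLDDT summaries, Kabsch superposition,
shape-based triage, and physico-chemical sequence properties.

Predicted structure models store the per-residue confidence (pLDDT,
0-100) in the B-factor column of their PDB files.  Models are reduced to
their C-alpha trace.  Superposition is least-squares rigid-body (Kabsch)
on an explicitly supplied atom pairing — the sequence-independent
aligner that produced the published superpositions is not reimplemented,
so figure-caption RMSDs are not directly comparable.  Candidate novel
folds are triaged by confidence (mean pLDDT), hit status, and a
gyration-tensor elongation score that flags long-helix (rod-like)
models.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy.optimize import brentq

logger = logging.getLogger(__name__)

PLDDT_BANDS = ("very_high", "confident", "low", "very_low")


@dataclass(frozen=True)
class ProteinModel:
    """C-alpha trace of one predicted model with per-residue pLDDT."""

    model_id: str
    residues: tuple[tuple[int, str, tuple[float, float, float], float], ...]

    def __post_init__(self) -> None:
        indices = [r[0] for r in self.residues]
        if any(b <= a for a, b in zip(indices, indices[1:])):
            raise ValueError("residue indices must be strictly increasing")

    @property
    def mean_plddt(self) -> float:
        return float(np.mean([r[3] for r in self.residues]))

    @property
    def coords(self) -> np.ndarray:
        return np.array([r[2] for r in self.residues], dtype=float)

    @property
    def sequence(self) -> str:
        return "".join(_THREE_TO_ONE.get(r[1], "X") for r in self.residues)


_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}


def parse_model(path: str | Path, model_id: Optional[str] = None) -> ProteinModel:
    """Read a PDB-format model into its C-alpha trace.

    One C-alpha per residue; for alternate locations the first one in
    file order is kept.  pLDDT is read from the B-factor column; values
    outside [0, 100] are kept with a warning.  A file without C-alpha
    ATOM records is an error.
    """
    from Bio.PDB import PDBParser

    path = Path(path)
    if model_id is None:
        model_id = path.stem
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # fixture files have no header
        structure = PDBParser(QUIET=True).get_structure(model_id, str(path))
    residues = []
    for residue in structure.get_residues():
        if "CA" not in residue:
            continue
        atom = residue["CA"]
        if atom.is_disordered():
            atom = atom.disordered_get_list()[0]
        plddt = float(atom.get_bfactor())
        if not 0.0 <= plddt <= 100.0:
            logger.warning(
                "%s residue %s: B-factor %.2f outside the pLDDT range [0, 100]",
                model_id,
                residue.id[1],
                plddt,
            )
        residues.append(
            (
                int(residue.id[1]),
                residue.get_resname().strip(),
                tuple(float(x) for x in atom.coord),
                plddt,
            )
        )
    if not residues:
        raise ValueError(f"{path}: no C-alpha ATOM records")
    return ProteinModel(model_id=model_id, residues=tuple(residues))


def plddt_band(p: float) -> str:
    """Confidence band of a pLDDT value.

    >90 very_high; (70, 90] confident; (50, 70] low; <=50 very_low.
    Boundaries are assigned to the lower band (upward-exclusive), a fixed
    convention since the canonical interval definitions are open.
    """
    if not 0.0 <= p <= 100.0:
        raise ValueError(f"pLDDT {p} outside [0, 100]")
    if p > 90:
        return "very_high"
    if p > 70:
        return "confident"
    if p > 50:
        return "low"
    return "very_low"


def band_fractions(model: ProteinModel) -> dict[str, float]:
    """Fraction of residues in each pLDDT confidence band."""
    n = len(model.residues)
    counts = {band: 0 for band in PLDDT_BANDS}
    for _, _, _, plddt in model.residues:
        counts[plddt_band(plddt)] += 1
    return {band: counts[band] / n for band in PLDDT_BANDS}


@dataclass(frozen=True)
class SuperpositionResult:
    rotation: np.ndarray  # 3x3 proper rotation
    translation: np.ndarray  # length-3
    rmsd: float
    n_atoms: int


def kabsch_superpose(
    a: Sequence[Sequence[float]] | np.ndarray,
    b: Sequence[Sequence[float]] | np.ndarray,
) -> SuperpositionResult:
    """Least-squares rigid superposition of paired point sets (a onto b).

    Returns the proper rotation R (reflections corrected by the
    determinant sign) and translation t minimizing
    ``sqrt(mean(|R a_i + t - b_i|^2))``, plus that RMSD.  Requires >= 3
    pairs of equal count.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise ValueError("point sets must be equal-shaped (n, 3) arrays")
    n = a.shape[0]
    if n < 3:
        raise ValueError("superposition requires at least 3 point pairs")
    centroid_a = a.mean(axis=0)
    centroid_b = b.mean(axis=0)
    aa = a - centroid_a
    bb = b - centroid_b
    h = aa.T @ bb
    u, _s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rotation = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    translation = centroid_b - rotation @ centroid_a
    residuals = (rotation @ a.T).T + translation - b
    rmsd = float(np.sqrt((residuals**2).sum() / n))
    return SuperpositionResult(
        rotation=rotation, translation=translation, rmsd=rmsd, n_atoms=n
    )


def elongation_score(coords: np.ndarray | ProteinModel) -> float:
    """Rod-likeness of a C-alpha trace: ratio of the two largest gyration
    tensor eigenvalues.

    ~1 for compact globular clouds, large (>> 10) for long helices.
    Returns ``inf`` when the second eigenvalue is (numerically) zero,
    i.e. collinear points.
    """
    if isinstance(coords, ProteinModel):
        coords = coords.coords
    coords = np.asarray(coords, dtype=float)
    if coords.shape[0] < 3:
        raise ValueError("elongation score requires at least 3 residues")
    centered = coords - coords.mean(axis=0)
    gyration = centered.T @ centered / coords.shape[0]
    eigenvalues = np.sort(np.linalg.eigvalsh(gyration))[::-1]
    lam1, lam2 = float(eigenvalues[0]), float(eigenvalues[1])
    if lam2 <= 1e-12 * max(lam1, 1.0):
        return math.inf
    return lam1 / lam2


# ---------------------------------------------------------------------------
# physico-chemical sequence properties

#: EMBOSS pKa set: the two termini plus the seven ionizable side chains.
PKA_TABLE = {
    "n_terminus": 8.6,
    "c_terminus": 3.6,
    "K": 10.8,
    "R": 12.5,
    "H": 6.5,
    "D": 3.9,
    "E": 4.1,
    "C": 8.5,
    "Y": 10.1,
}

_POSITIVE = ("K", "R", "H")
_NEGATIVE = ("D", "E", "C", "Y")


@dataclass(frozen=True)
class PhysChemProfile:
    gravy: float
    isoelectric_point: float
    instability_index: float


def net_charge(
    sequence: str, ph: float, pka: Mapping[str, float] = PKA_TABLE
) -> float:
    """Henderson-Hasselbalch net charge of a peptide at a given pH."""
    counts = {aa: sequence.count(aa) for aa in _POSITIVE + _NEGATIVE}
    charge = 1.0 / (1.0 + 10 ** (ph - pka["n_terminus"]))
    charge -= 1.0 / (1.0 + 10 ** (pka["c_terminus"] - ph))
    for aa in _POSITIVE:
        charge += counts[aa] / (1.0 + 10 ** (ph - pka[aa]))
    for aa in _NEGATIVE:
        charge -= counts[aa] / (1.0 + 10 ** (pka[aa] - ph))
    return charge


def isoelectric_point(
    sequence: str, pka: Mapping[str, float] = PKA_TABLE
) -> float:
    """pH at which the peptide's net charge is zero (Brent root finding).

    The charge function is strictly decreasing in pH, so the root is
    unique; it is located to |net charge| < 1e-4.
    """
    return float(
        brentq(lambda ph: net_charge(sequence, ph, pka), 0.001, 13.999, xtol=1e-10)
    )


def physchem(sequence: str, max_unknown_fraction: float = 0.10) -> PhysChemProfile:
    """GRAVY, isoelectric point and instability index of a protein.

    GRAVY is the mean Kyte-Doolittle hydropathy; the instability index is
    ``(10 / L) * sum`` of the published dipeptide instability weights
    (DIWV).  Residues outside the 20 standard amino acids are skipped,
    but more than ``max_unknown_fraction`` of them is an error.
    """
    from Bio.SeqUtils.ProtParamData import DIWV, kd

    if not sequence:
        raise ValueError("empty sequence")
    sequence = sequence.upper()
    known = [aa for aa in sequence if aa in kd]
    if len(sequence) - len(known) > max_unknown_fraction * len(sequence):
        raise ValueError(
            f"more than {max_unknown_fraction:.0%} unknown residues in sequence"
        )
    if len(known) < 2:
        raise ValueError("need at least 2 standard residues")
    clean = "".join(known)
    gravy = sum(kd[aa] for aa in clean) / len(clean)
    dipeptide_sum = sum(
        DIWV[clean[i]][clean[i + 1]] for i in range(len(clean) - 1)
    )
    instability = dipeptide_sum * 10.0 / len(clean)
    return PhysChemProfile(
        gravy=gravy,
        isoelectric_point=isoelectric_point(clean),
        instability_index=instability,
    )


# ---------------------------------------------------------------------------
# novel-fold triage

@dataclass(frozen=True)
class TriageResult:
    """Partition of unannotated, well-folded models.

    ``no_hit`` — no structure-search hit at all; ``below_cutoff`` — hits
    exist but none survived annotation transfer (in the standard pipeline
    that means the best hit fell below the bit-score cutoff; a passing
    hit whose target lacked annotation lands here too).  Each group is
    split into helix-like (rod) and globular candidates by the
    elongation score.
    """

    no_hit_helix: tuple[str, ...]
    no_hit_globular: tuple[str, ...]
    below_cutoff_helix: tuple[str, ...]
    below_cutoff_globular: tuple[str, ...]
    skipped_no_model: tuple[str, ...]


def novel_fold_triage(
    assignments: Iterable["MorphologAssignment"],
    models: Mapping[str, ProteinModel],
    plddt_min: float = 70.0,
    elongation_max: float = 10.0,
) -> TriageResult:
    """Select unannotated well-folded proteins and partition them.

    A protein qualifies when it has no transferred annotation and its
    model's mean pLDDT exceeds ``plddt_min``.  Proteins without a model
    are collected in ``skipped_no_model``.  Output lists are sorted, so
    the partition is independent of input order.
    """
    groups: dict[str, list[str]] = {
        "no_hit_helix": [],
        "no_hit_globular": [],
        "below_cutoff_helix": [],
        "below_cutoff_globular": [],
        "skipped": [],
    }
    for asg in assignments:
        if asg.transferred is not None:
            continue
        model = models.get(asg.query_id)
        if model is None:
            groups["skipped"].append(asg.query_id)
            continue
        if model.mean_plddt <= plddt_min:
            continue
        hit_group = "no_hit" if asg.overall_best is None else "below_cutoff"
        shape = (
            "helix" if elongation_score(model) >= elongation_max else "globular"
        )
        groups[f"{hit_group}_{shape}"].append(asg.query_id)
    return TriageResult(
        no_hit_helix=tuple(sorted(groups["no_hit_helix"])),
        no_hit_globular=tuple(sorted(groups["no_hit_globular"])),
        below_cutoff_helix=tuple(sorted(groups["below_cutoff_helix"])),
        below_cutoff_globular=tuple(sorted(groups["below_cutoff_globular"])),
        skipped_no_model=tuple(sorted(groups["skipped"])),
    )
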