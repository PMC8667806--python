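"""Readers and writers for peak lists, reference structures and torsion tables.

The native peak-list format is a TSV with one row per candidate
interpretation::

    peak_id  res_i  atom_i  res_j  atom_j  upper_bound_A  padded  source

Rows sharing a ``peak_id`` (contiguously) form one peak; interpretation
order within a peak is the row order. A ``casp13`` dialect accepts a looser
whitespace table (``id res_i atom_i res_j atom_j [dist]``, ``#`` comments)
for ingesting externally curated NOE lists.

Residue indices are 1-based at every interface, following PDB convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "Interpretation",
    "Peak",
    "ReferenceStructure",
    "TorsionPrediction",
    "PeakListParseError",
    "read_peak_list",
    "write_peak_list",
    "read_reference_structure",
    "write_ca_pdb",
    "read_torsion_table",
    "write_torsion_table",
    "DEFAULT_UPPER_BOUND",
]

#: NOE upper bound assumed when a file does not state one: hydrogen pairs
#: within ~6 Å give rise to an observable NOESY signal.
DEFAULT_UPPER_BOUND = 6.0

PEAK_LIST_COLUMNS = [
    "peak_id",
    "res_i",
    "atom_i",
    "res_j",
    "atom_j",
    "upper_bound_A",
    "padded",
    "source",
]


class PeakListParseError(ValueError):
    """Raised when a peak-list file cannot be parsed; carries the line number."""


@dataclass(frozen=True)
class Interpretation:
    """One candidate atom pair that could give rise to a NOESY signal.

    ``upper_bound`` is the NOE-derived distance ceiling in Å;
    ``pseudoatom_padded`` records whether degenerate hydrogens were already
    collapsed onto their bonded heavy atom (with the bound padded).
    """

    residue_i: int
    atom_i: str
    residue_j: int
    atom_j: str
    upper_bound: float = DEFAULT_UPPER_BOUND
    pseudoatom_padded: bool = False

    def __post_init__(self) -> None:
        if self.residue_i < 1 or self.residue_j < 1:
            raise ValueError("residue indices are 1-based and must be ≥ 1")
        if not self.upper_bound > 0:
            raise ValueError("upper_bound must be positive")

    @property
    def separation(self) -> int:
        return abs(self.residue_i - self.residue_j)

    def residue_pair(self) -> tuple[int, int]:
        return (min(self.residue_i, self.residue_j), max(self.residue_i, self.residue_j))


@dataclass
class Peak:
    """One NOESY signal with its ambiguity list of candidate interpretations."""

    peak_id: str
    interpretations: list[Interpretation]
    source: str = "experimental"

    def __post_init__(self) -> None:
        if not self.interpretations:
            raise ValueError(f"peak {self.peak_id!r} has no interpretations")
        if self.source not in ("experimental", "synthetic"):
            raise ValueError(f"unknown peak source {self.source!r}")


@dataclass
class TorsionPrediction:
    """Chemical-shift-derived backbone dihedral prediction for one residue."""

    residue: int
    phi_center: float
    psi_center: float
    phi_halfwidth: float
    psi_halfwidth: float
    confidence: float = 1.0

    def __post_init__(self) -> None:
        if self.phi_halfwidth <= 0 or self.psi_halfwidth <= 0:
            raise ValueError("halfwidths must be positive")
        for name in ("phi_center", "psi_center"):
            a = getattr(self, name)
            if not (-180.0 < a <= 180.0):
                raise ValueError(f"{name}={a} outside (−180, 180]")


class ReferenceStructure:
    """A reference (e.g. native) structure: sequence plus an atom table.

    The atom table is a DataFrame with columns ``res`` (1-based index),
    ``atom``, ``x``, ``y``, ``z`` (Å).
    """

    def __init__(self, sequence: str, atoms: pd.DataFrame):
        self.sequence = sequence
        self.atoms = atoms.reset_index(drop=True)
        if len(self.atoms):
            bad = ~self.atoms["res"].between(1, len(sequence))
            if bad.any():
                raise ValueError("atom table contains residue indices outside sequence")
            xyz = self.atoms[["x", "y", "z"]].to_numpy(float)
            if not np.all(np.isfinite(xyz)):
                raise ValueError("non-finite coordinates in atom table")
        self._index: dict[tuple[int, str], np.ndarray] = {
            (int(r.res), str(r.atom)): np.array([r.x, r.y, r.z])
            for r in self.atoms.itertuples()
        }

    def __len__(self) -> int:
        return len(self.sequence)

    def atom_coord(self, residue: int, atom: str) -> np.ndarray | None:
        """Coordinates of (residue, atom), or None if absent."""
        return self._index.get((residue, atom))

    def ca_coords(self) -> np.ndarray:
        ca = self.atoms[self.atoms["atom"] == "CA"].sort_values("res")
        return ca[["x", "y", "z"]].to_numpy(float)

    def distance(self, residue_i: int, atom_i: str, residue_j: int, atom_j: str) -> float | None:
        a = self.atom_coord(residue_i, atom_i)
        b = self.atom_coord(residue_j, atom_j)
        if a is None or b is None:
            return None
        return float(np.linalg.norm(a - b))


# ---------------------------------------------------------------------------
# peak lists


def _parse_bool(tok: str) -> bool:
    return tok.strip().lower() in ("1", "true", "t", "yes")


def read_peak_list(path: str | Path, dialect: str = "tsv") -> list[Peak]:
    """Parse a peak list. ``dialect`` is ``tsv`` (native) or ``casp13``.

    Every input row is either parsed or reported with its line number;
    a ``peak_id`` that reappears after a different peak intervened is a
    validation error.
    """
    path = Path(path)
    if dialect not in ("tsv", "casp13"):
        raise ValueError(f"unsupported dialect {dialect!r}")
    rows: list[tuple[str, Interpretation, str]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if dialect == "casp13" and line.lstrip().startswith("#"):
                continue
            toks = line.split("\t") if dialect == "tsv" else line.split()
            if dialect == "tsv" and lineno == 1 and toks[0] == "peak_id":
                continue  # header
            try:
                if dialect == "tsv":
                    pid, ri, ai, rj, aj, ub = toks[:6]
                    padded = _parse_bool(toks[6]) if len(toks) > 6 else False
                    source = toks[7] if len(toks) > 7 else "experimental"
                else:
                    pid, ri, ai, rj, aj = toks[:5]
                    ub = toks[5] if len(toks) > 5 else str(DEFAULT_UPPER_BOUND)
                    padded, source = False, "experimental"
                interp = Interpretation(
                    residue_i=int(ri),
                    atom_i=ai,
                    residue_j=int(rj),
                    atom_j=aj,
                    upper_bound=float(ub),
                    pseudoatom_padded=padded,
                )
            except (ValueError, IndexError) as exc:
                raise PeakListParseError(
                    f"{path.name}: malformed line {lineno}: {line!r} ({exc})"
                ) from exc
            rows.append((pid, interp, source))

    peaks: list[Peak] = []
    seen: set[str] = set()
    current_id: str | None = None
    for pid, interp, source in rows:
        if pid != current_id:
            if pid in seen:
                raise PeakListParseError(
                    f"{path.name}: duplicate peak_id {pid!r} (non-contiguous reuse)"
                )
            seen.add(pid)
            peaks.append(Peak(peak_id=pid, interpretations=[interp], source=source))
            current_id = pid
        else:
            peaks[-1].interpretations.append(interp)
    return peaks


def write_peak_list(peaks: Iterable[Peak], path: str | Path) -> None:
    """Write the native TSV dialect; round-trips bit-for-bit through read_peak_list."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("\t".join(PEAK_LIST_COLUMNS) + "\n")
        for p in peaks:
            for it in p.interpretations:
                fh.write(
                    "\t".join(
                        [
                            p.peak_id,
                            str(it.residue_i),
                            it.atom_i,
                            str(it.residue_j),
                            it.atom_j,
                            repr(float(it.upper_bound)),
                            "1" if it.pseudoatom_padded else "0",
                            p.source,
                        ]
                    )
                    + "\n"
                )


# ---------------------------------------------------------------------------
# structures

_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
_ONE_TO_THREE = {v: k for k, v in _THREE_TO_ONE.items()}


def read_reference_structure(path: str | Path, model_index: int = 1) -> ReferenceStructure:
    """Read one model of a PDB file into a ReferenceStructure.

    ``model_index`` is 1-based. Residues lacking a Cα are skipped with a
    warning; a file with no standard amino-acid atoms is an error.
    """
    from Bio.PDB import PDBParser

    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("ref", str(path))
    models = list(structure)
    if not models:
        raise ValueError(f"{path}: no models found")
    if model_index < 1 or model_index > len(models):
        raise ValueError(f"{path}: model {model_index} requested, file has {len(models)}")
    model = models[model_index - 1]

    seq: list[str] = []
    records: list[tuple[int, str, float, float, float]] = []
    idx = 0
    for chain in model:
        for res in chain:
            if res.id[0] != " " or res.get_resname() not in _THREE_TO_ONE:
                continue
            if "CA" not in res:
                warnings.warn(
                    f"{Path(path).name}: residue {res.get_resname()}{res.id[1]} lacks CA; skipped"
                )
                continue
            idx += 1
            seq.append(_THREE_TO_ONE[res.get_resname()])
            for atom in res:
                x, y, z = atom.coord
                records.append((idx, atom.get_name(), float(x), float(y), float(z)))
    if not records:
        raise ValueError(f"{path}: no standard protein atoms found")
    atoms = pd.DataFrame(records, columns=["res", "atom", "x", "y", "z"])
    return ReferenceStructure("".join(seq), atoms)


def write_ca_pdb(
    frames: "np.ndarray | list[np.ndarray]", sequence: str, path: str | Path
) -> None:
    """Write one or more Cα-only models as a (multi-model) PDB file."""
    if isinstance(frames, np.ndarray) and frames.ndim == 2:
        frames = [frames]
    with open(Path(path), "w") as fh:
        for m, coords in enumerate(frames, start=1):
            fh.write(f"MODEL     {m:4d}\n")
            for i, (x, y, z) in enumerate(np.asarray(coords, float), start=1):
                resname = _ONE_TO_THREE.get(sequence[i - 1], "ALA") if sequence else "ALA"
                fh.write(
                    f"ATOM  {i:5d}  CA  {resname} A{i:4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C\n"
                )
            fh.write("ENDMDL\n")
        fh.write("END\n")


# ---------------------------------------------------------------------------
# torsion tables

TORSION_COLUMNS = [
    "residue", "phi_center", "psi_center", "phi_halfwidth", "psi_halfwidth", "confidence",
]


def read_torsion_table(path: str | Path) -> list[TorsionPrediction]:
    """Read a TALOS-like columnar table of backbone dihedral predictions.

    Confidence values outside [0, 1] are clamped with a warning; a
    non-numeric angle is a parse error.
    """
    path = Path(path)
    out: list[TorsionPrediction] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            toks = line.split("\t") if "\t" in line else line.split()
            if lineno == 1 and toks[0] == "residue":
                continue
            try:
                res = int(toks[0])
                phi_c, psi_c, phi_h, psi_h = (float(t) for t in toks[1:5])
                conf = float(toks[5]) if len(toks) > 5 else 1.0
            except (ValueError, IndexError) as exc:
                raise PeakListParseError(
                    f"{path.name}: malformed torsion row at line {lineno}: {line!r}"
                ) from exc
            if not 0.0 <= conf <= 1.0:
                warnings.warn(
                    f"{path.name}: line {lineno}: confidence {conf} clamped to [0, 1]"
                )
                conf = min(1.0, max(0.0, conf))
            out.append(TorsionPrediction(res, phi_c, psi_c, phi_h, psi_h, conf))
    return out


def write_torsion_table(preds: Iterable[TorsionPrediction], path: str | Path) -> None:
    with open(Path(path), "w") as fh:
        fh.write("\t".join(TORSION_COLUMNS) + "\n")
        for p in preds:
            fh.write(
                f"{p.residue}\t{p.phi_center!r}\t{p.psi_center!r}\t"
                f"{p.phi_halfwidth!r}\t{p.psi_halfwidth!r}\t{p.confidence!r}\n"
            )
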