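"""Dataset curation: sequence-separation filtering, pseudoatom mapping,
true-contact filtering against a reference structure, and k-means contact
clustering.

A raw ambiguous NOESY peak list is turned into the standard dataset family:

* the *4-residue ambiguous* dataset drops every peak with any interpretation
  between residues closer than 4 apart in sequence (short-range contacts are
  almost always satisfiable and therefore carry no structural information
  while being able to absorb noise);
* the *1-residue ambiguous* dataset drops only intra-residue interpretations;
* a *true* dataset keeps only interpretations satisfied in a reference
  structure (for benchmarking);
* a *clustered* dataset reduces the true contacts to k representative
  contacts via k-means on residue-index pairs.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np

from .io_formats import Interpretation, Peak, ReferenceStructure

__all__ = [
    "CurationReport",
    "filter_by_sequence_separation",
    "map_pseudoatoms",
    "filter_true_against_reference",
    "cluster_contacts",
    "curation_summary",
]


@dataclass
class CurationReport:
    """Bookkeeping for one curated dataset (counts and true-peak fraction)."""

    dataset_name: str
    total_peaks: int
    true_peaks: int | None = None
    true_fraction: float | None = None
    removed_peaks: int = 0
    notes: str = ""


# ---------------------------------------------------------------------------
# sequence-separation filter


def filter_by_sequence_separation(peaks: list[Peak], min_separation: int) -> list[Peak]:
    """Drop every peak with ANY interpretation at |i−j| < min_separation.

    A single short-range interpretation removes the whole peak: short-range
    contacts are trivially satisfiable by the chain and would let noisy
    peaks be "explained away" rather than rejected. ``min_separation=4``
    builds the 4-residue dataset, ``min_separation=1`` the 1-residue one.
    """
    if min_separation < 0:
        raise ValueError("min_separation must be ≥ 0")
    return [
        p
        for p in peaks
        if all(it.separation >= min_separation for it in p.interpretations)
    ]


# ---------------------------------------------------------------------------
# pseudoatom mapping

_BACKBONE_H = {"H": "N", "HN": "N", "H1": "N", "H2": "N", "H3": "N",
               "HA": "CA", "HA2": "CA", "HA3": "CA"}

# residue-typed exceptions: side-chain hydrogens bonded to N/O/S heavy atoms
_POLAR_SIDECHAIN_H: dict[str, dict[str, str]] = {
    "N": {"HD21": "ND2", "HD22": "ND2"},
    "Q": {"HE21": "NE2", "HE22": "NE2"},
    "K": {"HZ1": "NZ", "HZ2": "NZ", "HZ3": "NZ"},
    "R": {"HE": "NE", "HH11": "NH1", "HH12": "NH1", "HH21": "NH2", "HH22": "NH2"},
    "S": {"HG": "OG"},
    "T": {"HG1": "OG1"},
    "Y": {"HH": "OH"},
    "C": {"HG": "SG"},
    "W": {"HE1": "NE1"},
    "H": {"HD1": "ND1", "HE2": "NE2"},
}

_GREEK = set("BGDEZH")


def _map_sidechain_carbon_h(name: str) -> str | None:
    """HD11 → CD1, HG21 → CG2, HB2 → CB, HB → CB; None if not recognisable."""
    if not name.startswith("H") or len(name) < 2 or name[1] not in _GREEK:
        return None
    rest = name[1:]
    pos, digits = rest[0], rest[1:]
    if digits and not digits.isdigit():
        return None
    if len(digits) >= 2:
        return "C" + pos + digits[0]  # branch index kept, H index dropped
    return "C" + pos


def _map_hydrogen(name: str, res_type: str | None) -> tuple[str, bool] | None:
    """Return (heavy atom, pad?) for a hydrogen atom name, or None if unknown."""
    if name in _BACKBONE_H:
        return _BACKBONE_H[name], False
    if res_type and name in _POLAR_SIDECHAIN_H.get(res_type, {}):
        return _POLAR_SIDECHAIN_H[res_type][name], True
    heavy = _map_sidechain_carbon_h(name)
    if heavy is not None:
        return heavy, True
    return None


def map_pseudoatoms(
    peaks: list[Peak], pad: float = 1.0, sequence: str | None = None
) -> list[Peak]:
    """Collapse hydrogen atom names onto their bonded heavy atoms.

    Side-chain hydrogens (methyls above all) are rewritten to the bonded
    heavy atom and the distance bound is padded by ``pad`` Å, absorbing the
    degeneracy of symmetric hydrogens. Backbone amide H maps to N and Hα to
    CA with no pad (no degeneracy is removed there). Idempotent: heavy-atom
    names and already-padded interpretations pass through unchanged.

    ``sequence`` (one-letter codes, 1-based indexing) enables residue-typed
    mapping of polar side-chain hydrogens (e.g. Lys HZ → NZ); without it
    those names fall back to the generic carbon rule or are left unchanged
    with a warning.
    """
    if pad < 0:
        raise ValueError("pad must be ≥ 0")

    def res_type(i: int) -> str | None:
        if sequence and 1 <= i <= len(sequence):
            return sequence[i - 1]
        return None

    out: list[Peak] = []
    for p in peaks:
        new_interps: list[Interpretation] = []
        for it in p.interpretations:
            if it.pseudoatom_padded or not (
                it.atom_i.startswith("H") or it.atom_j.startswith("H")
            ):
                new_interps.append(it)
                continue
            names, padded_any, ok = [], False, True
            for atom, res in ((it.atom_i, it.residue_i), (it.atom_j, it.residue_j)):
                if atom.startswith("H"):
                    mapped = _map_hydrogen(atom, res_type(res))
                    if mapped is None:
                        warnings.warn(
                            f"peak {p.peak_id}: unknown hydrogen atom name {atom!r}; "
                            "interpretation left unchanged"
                        )
                        ok = False
                        break
                    heavy, padded = mapped
                    names.append(heavy)
                    padded_any = padded_any or padded
                else:
                    names.append(atom)
            if not ok:
                new_interps.append(it)
                continue
            new_interps.append(
                replace(
                    it,
                    atom_i=names[0],
                    atom_j=names[1],
                    upper_bound=it.upper_bound + (pad if padded_any else 0.0),
                    pseudoatom_padded=True,
                )
            )
        out.append(Peak(p.peak_id, new_interps, p.source))
    return out


# ---------------------------------------------------------------------------
# true-contact filtering


def filter_true_against_reference(
    peaks: list[Peak], ref: ReferenceStructure, dataset_name: str = "true"
) -> tuple[list[Peak], CurationReport]:
    """Keep only interpretations satisfied in the reference structure.

    An interpretation survives iff its reference-structure distance is
    ≤ its upper bound; peaks with no surviving interpretation are dropped
    and counted as false. Unresolvable atoms are excluded with a warning.
    """
    kept: list[Peak] = []
    for p in peaks:
        survivors = []
        for it in p.interpretations:
            d = ref.distance(it.residue_i, it.atom_i, it.residue_j, it.atom_j)
            if d is None:
                warnings.warn(
                    f"peak {p.peak_id}: atom {it.atom_i}@{it.residue_i} or "
                    f"{it.atom_j}@{it.residue_j} not found in reference; excluded"
                )
                continue
            if d <= it.upper_bound:
                survivors.append(it)
        if survivors:
            kept.append(Peak(p.peak_id, survivors, p.source))
    total = len(peaks)
    report = CurationReport(
        dataset_name=dataset_name,
        total_peaks=total,
        true_peaks=len(kept),
        true_fraction=(len(kept) / total) if total else None,
        removed_peaks=total - len(kept),
    )
    return kept, report


# ---------------------------------------------------------------------------
# contact clustering


def cluster_contacts(
    contacts: list[Interpretation], k: int, seed: int = 0
) -> list[Interpretation]:
    """Reduce a contact set to ≤ k representatives by k-means in index space.

    The feature vector of a contact is its sorted residue-index pair; the
    representative of each cluster is the actual member nearest the cluster
    mean (ties to the lowest input index), so outputs are always real
    contacts. Deterministic given ``seed``.
    """
    from sklearn.cluster import KMeans

    if k < 1:
        raise ValueError("k must be ≥ 1")
    if not contacts:
        raise ValueError("contacts must be non-empty")
    feats = np.array([c.residue_pair() for c in contacts], dtype=float)
    n_distinct = len(np.unique(feats, axis=0))
    n_clusters = min(k, n_distinct)
    if n_clusters >= len(contacts):
        return list(contacts)
    km = KMeans(n_clusters=n_clusters, n_init=10, random_state=seed)
    labels = km.fit_predict(feats)
    reps: list[Interpretation] = []
    for c in range(n_clusters):
        members = np.flatnonzero(labels == c)
        d = np.linalg.norm(feats[members] - km.cluster_centers_[c], axis=1)
        reps.append(contacts[members[int(np.argmin(d))]])
    return reps


# ---------------------------------------------------------------------------
# summary


def curation_summary(
    peaks_by_dataset: dict[str, list[Peak]], ref: ReferenceStructure | None = None
) -> list[CurationReport]:
    """One CurationReport per dataset; true columns only when a reference is given."""
    reports = []
    for name, peaks in peaks_by_dataset.items():
        if ref is None or not peaks:
            reports.append(
                CurationReport(
                    dataset_name=name,
                    total_peaks=len(peaks),
                    notes="" if peaks else "empty dataset",
                )
            )
        else:
            _, rep = filter_true_against_reference(peaks, ref, dataset_name=name)
            reports.append(rep)
    return reports


def reports_to_tsv(reports: list[CurationReport], path) -> None:
    import pandas as pd

    pd.DataFrame([vars(r) for r in reports]).to_csv(path, sep="\t", index=False)
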