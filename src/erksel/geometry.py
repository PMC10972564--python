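"""Structural geometry: superposition, per-residue RMSD, halogen-pi distances.

Reproduces the structural comparisons used for kinase conformational
analysis: least-squares (Kabsch) superposition on a C-terminal-domain
Calpha selection (ERK2 residues 109-141, 205-245, 272-310), per-residue
RMSD between superposed models with a configurable atom subset, and the
distance from a ligand halogen atom to the centroid of a tyrosine
aromatic ring (the Cl-pi contact convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np

__all__ = [
    "Atom",
    "StructureModel",
    "SelectionSpec",
    "SuperpositionResult",
    "read_structure",
    "kabsch_superpose",
    "apply_transform",
    "residue_rmsd",
    "cl_pi_distance",
    "TYROSINE_RING_ATOMS",
    "C_DOMAIN_RANGES",
]

#: Calpha ranges of the ERK2 C-terminal domain used for superposition.
C_DOMAIN_RANGES = ((109, 141), (205, 245), (272, 310))

TYROSINE_RING_ATOMS = ("CG", "CD1", "CD2", "CE1", "CE2", "CZ")

_BACKBONE = {"N", "CA", "C", "O", "OXT"}


@dataclass(frozen=True)
class Atom:
    chain_id: str
    residue_number: int
    residue_name: str
    atom_name: str
    element: str
    occupancy: float
    coords: tuple[float, float, float]
    altloc: str = ""


@dataclass
class StructureModel:
    """Atomic coordinates with author residue numbering."""

    atoms: list[Atom]
    name: str = ""
    _index: dict[tuple[str, int, str], Atom] = field(
        default_factory=dict, repr=False
    )

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ValueError("empty structure model")
        for atom in self.atoms:
            if not all(np.isfinite(atom.coords)):
                raise ValueError("non-finite coordinates")
            self._index[(atom.chain_id, atom.residue_number, atom.atom_name)] = atom

    def get(self, chain_id: str, residue_number: int, atom_name: str) -> Atom | None:
        return self._index.get((chain_id, residue_number, atom_name))

    @property
    def chains(self) -> list[str]:
        seen: dict[str, None] = {}
        for a in self.atoms:
            seen.setdefault(a.chain_id, None)
        return list(seen)

    def residue_atoms(self, chain_id: str, residue_number: int) -> list[Atom]:
        return [
            a
            for a in self.atoms
            if a.chain_id == chain_id and a.residue_number == residue_number
        ]


@dataclass(frozen=True)
class SelectionSpec:
    """An atom selection by chain, residue ranges, and atom names.

    ``numbering_offset`` is added to the selection's residue numbers
    before lookup, absorbing construct/tag numbering shifts between
    entries.
    """

    residue_ranges: tuple[tuple[int, int], ...] = C_DOMAIN_RANGES
    chain_id: str | None = None
    atom_names: tuple[str, ...] = ("CA",)
    numbering_offset: int = 0

    def __post_init__(self) -> None:
        ranges = sorted(self.residue_ranges)
        for (s1, e1), (s2, e2) in zip(ranges, ranges[1:]):
            if s2 <= e1:
                raise ValueError("residue ranges must not overlap")

    def residues(self) -> list[int]:
        out: list[int] = []
        for start, end in self.residue_ranges:
            out.extend(range(start + self.numbering_offset,
                             end + self.numbering_offset + 1))
        return out


@dataclass(frozen=True)
class SuperpositionResult:
    rotation: np.ndarray
    translation: np.ndarray
    rmsd_fit: float
    n_atoms: int


def read_structure(path, fmt: str | None = None) -> StructureModel:
    """Read a PDB or mmCIF file into a :class:`StructureModel`.

    Hydrogens (and deuteriums) are dropped; of alternate conformations
    only the highest-occupancy altloc of each atom is retained; waters
    are kept.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt is None:
        st = gemmi.read_structure(str(path))
    else:
        coor_format = {
            "PDB": gemmi.CoorFormat.Pdb,
            "mmCIF": gemmi.CoorFormat.Mmcif,
        }[fmt]
        st = gemmi.read_structure(str(path), format=coor_format)
    st.setup_entities()
    if len(st) == 0:
        raise ValueError(f"{path}: no models")
    model = st[0]
    atoms: list[Atom] = []
    for chain in model:
        for residue in chain:
            best: dict[str, gemmi.Atom] = {}
            for atom in residue:
                if atom.element.is_hydrogen:
                    continue
                prev = best.get(atom.name)
                if prev is None or atom.occ > prev.occ:
                    best[atom.name] = atom
            for atom in best.values():
                atoms.append(
                    Atom(
                        chain_id=chain.name,
                        residue_number=residue.seqid.num,
                        residue_name=residue.name,
                        atom_name=atom.name,
                        element=atom.element.name,
                        occupancy=atom.occ,
                        coords=(atom.pos.x, atom.pos.y, atom.pos.z),
                        altloc=atom.altloc,
                    )
                )
    if not atoms:
        raise ValueError(f"{path}: empty model")
    return StructureModel(atoms=atoms, name=path.stem)


def _selected_coords(
    model: StructureModel, selection: SelectionSpec
) -> tuple[np.ndarray, list[tuple[int, str]]]:
    chain = selection.chain_id or model.chains[0]
    coords: list[tuple[float, float, float]] = []
    missing: list[tuple[int, str]] = []
    for resnum in selection.residues():
        for atom_name in selection.atom_names:
            atom = model.get(chain, resnum, atom_name)
            if atom is None:
                missing.append((resnum, atom_name))
            else:
                coords.append(atom.coords)
    return np.asarray(coords, float), missing


def _kabsch(ref: np.ndarray, mob: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal proper rotation R and translation t with x' = R x + t."""
    ref_c = ref.mean(axis=0)
    mob_c = mob.mean(axis=0)
    h = (mob - mob_c).T @ (ref - ref_c)
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rotation = vt.T @ corr @ u.T
    translation = ref_c - rotation @ mob_c
    moved = mob @ rotation.T + translation
    rmsd = float(np.sqrt(np.mean(np.sum((moved - ref) ** 2, axis=1))))
    return rotation, translation, rmsd


def kabsch_superpose(
    reference: StructureModel,
    mobile: StructureModel,
    selection: SelectionSpec = SelectionSpec(),
    mobile_selection: SelectionSpec | None = None,
) -> SuperpositionResult:
    """Least-squares rigid superposition of ``mobile`` onto ``reference``.

    ``mobile_selection`` allows a different chain or numbering offset on
    the mobile side; residue ranges must correspond pairwise.  Reflection
    solutions are excluded by the determinant sign correction, so the
    rotation is always proper.
    """
    ref_coords, ref_missing = _selected_coords(reference, selection)
    mob_coords, mob_missing = _selected_coords(
        mobile, mobile_selection or selection
    )
    problems = []
    if ref_missing:
        problems.append(f"reference missing {ref_missing[:8]}")
    if mob_missing:
        problems.append(f"mobile missing {mob_missing[:8]}")
    if problems:
        raise ValueError("superposition selection incomplete: " + "; ".join(problems))
    if len(ref_coords) < 3:
        raise ValueError("need at least 3 paired atoms")
    rotation, translation, rmsd = _kabsch(ref_coords, mob_coords)
    return SuperpositionResult(
        rotation=rotation,
        translation=translation,
        rmsd_fit=rmsd,
        n_atoms=len(ref_coords),
    )


def apply_transform(
    model: StructureModel, result: SuperpositionResult
) -> StructureModel:
    """Return a copy of ``model`` with the rigid transform applied."""
    atoms = []
    for a in model.atoms:
        xyz = result.rotation @ np.asarray(a.coords) + result.translation
        atoms.append(
            Atom(a.chain_id, a.residue_number, a.residue_name, a.atom_name,
                 a.element, a.occupancy, tuple(float(v) for v in xyz), a.altloc)
        )
    return StructureModel(atoms=atoms, name=model.name)


def residue_rmsd(
    reference: StructureModel,
    mobile_superposed: StructureModel,
    residue_number: int,
    atom_subset: str = "ALL_HEAVY",
    chain_id: str | None = None,
    mobile_chain_id: str | None = None,
    mobile_residue_number: int | None = None,
) -> float:
    """RMSD (A) over one residue's matched atoms, after global superposition.

    No per-residue refit is performed.  ``atom_subset`` is one of
    ``ALL_HEAVY``, ``SIDECHAIN_HEAVY``, or ``CA``; the atom-name
    intersection of the two residues is used.
    """
    ref_chain = chain_id or reference.chains[0]
    mob_chain = mobile_chain_id or chain_id or mobile_superposed.chains[0]
    mob_resnum = mobile_residue_number or residue_number
    ref_atoms = {a.atom_name: a for a in reference.residue_atoms(ref_chain, residue_number)}
    mob_atoms = {
        a.atom_name: a for a in mobile_superposed.residue_atoms(mob_chain, mob_resnum)
    }
    names = set(ref_atoms) & set(mob_atoms)
    if atom_subset == "CA":
        names &= {"CA"}
    elif atom_subset == "SIDECHAIN_HEAVY":
        names -= _BACKBONE
    elif atom_subset != "ALL_HEAVY":
        raise ValueError(f"unknown atom_subset {atom_subset!r}")
    if not names:
        raise ValueError(
            f"residue {residue_number}: empty atom intersection for {atom_subset}"
        )
    ref_xyz = np.array([ref_atoms[n].coords for n in sorted(names)])
    mob_xyz = np.array([mob_atoms[n].coords for n in sorted(names)])
    return float(np.sqrt(np.mean(np.sum((ref_xyz - mob_xyz) ** 2, axis=1))))


def cl_pi_distance(
    structure: StructureModel,
    halogen: tuple[str, int | str, str],
    tyrosine_residue: int,
    tyrosine_chain: str | None = None,
) -> float:
    """Distance (A) from a halogen atom to a tyrosine ring centroid.

    ``halogen`` is (chain_id, residue number or residue name, atom_name);
    the centroid is the unweighted mean of the six ring carbons.
    """
    chain, res_spec, atom_name = halogen
    hal_atom = None
    for a in structure.atoms:
        if a.chain_id != chain or a.atom_name != atom_name:
            continue
        if isinstance(res_spec, int):
            if a.residue_number == res_spec:
                hal_atom = a
                break
        elif a.residue_name == res_spec:
            hal_atom = a
            break
    if hal_atom is None:
        raise ValueError(f"halogen atom {halogen} not found")
    tyr_chain = tyrosine_chain or chain
    ring = []
    for name in TYROSINE_RING_ATOMS:
        atom = structure.get(tyr_chain, tyrosine_residue, name)
        if atom is None:
            raise ValueError(
                f"tyrosine {tyrosine_residue} missing ring atom {name}"
            )
        ring.append(atom.coords)
    centroid = np.mean(np.asarray(ring), axis=0)
    return float(np.linalg.norm(np.asarray(hal_atom.coords) - centroid))
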