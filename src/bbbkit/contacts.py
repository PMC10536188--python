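"""Post-docking ligand-protein contact mapping and classification.

A residue is "in contact" with the ligand when any heavy-atom pair falls
below a distance cutoff (default 0.38 nm, a value that captures both polar
interactions and the longer nonpolar carbon-carbon contacts).  Contacts are
then classified by distance windows alone (no angular criteria):

* hydrogen_bond - O/N ligand atom vs O/N residue atom within 0.25-0.35 nm
  (typical donor-acceptor range);
* nonpolar_CC  - carbon-carbon pair within 0.30-0.38 nm;
* CH_pi        - ligand aliphatic carbon within the cutoff of an aromatic
  ring atom of Phe/Tyr/Trp/His (ring membership from a packaged
  per-residue atom-name table);
* other_polar  - residues in contact that match none of the above.

All distances are heavy-atom distances in nm; hydrogens are parsed and
retained but never enter classification.
"""

from __future__ import annotations

import io
import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from Bio.PDB import PDBParser
from Bio.PDB.PDBExceptions import PDBConstructionWarning

logger = logging.getLogger(__name__)

#: Default heavy-atom contact cutoff, nm.
CONTACT_CUTOFF_NM = 0.38
#: Hydrogen-bond donor-acceptor window, nm (closed on both ends).
HBOND_WINDOW_NM = (0.25, 0.35)
#: Nonpolar carbon-carbon contact window, nm (closed on both ends).
CC_WINDOW_NM = (0.30, 0.38)

#: Aromatic ring atom names per residue type (side-chain rings).
AROMATIC_RING_ATOMS: dict[str, frozenset[str]] = {
    "PHE": frozenset({"CG", "CD1", "CD2", "CE1", "CE2", "CZ"}),
    "TYR": frozenset({"CG", "CD1", "CD2", "CE1", "CE2", "CZ"}),
    "TRP": frozenset({"CG", "CD1", "NE1", "CD2", "CE2", "CE3",
                      "CZ2", "CZ3", "CH2"}),
    "HIS": frozenset({"CG", "ND1", "CD2", "CE1", "NE2"}),
}

#: Covalent-neighbour distance used to spot polar-bonded ligand carbons, nm.
_BOND_CUTOFF_NM = 0.17

POLAR_ELEMENTS = frozenset({"N", "O"})


@dataclass(frozen=True)
class Atom:
    serial: int
    element: str
    name: str
    residue_name: str
    residue_number: int
    chain: str
    xyz: tuple[float, float, float]  # nm

    @property
    def is_hydrogen(self) -> bool:
        return self.element in ("H", "D")


@dataclass
class StructureModel:
    """Flat atom list with a ligand selector (residue name or chain id)."""

    atoms: list[Atom]
    ligand_resname: str | None = None
    ligand_chain: str | None = None

    def _is_ligand(self, atom: Atom) -> bool:
        if self.ligand_resname is not None:
            return atom.residue_name == self.ligand_resname
        if self.ligand_chain is not None:
            return atom.chain == self.ligand_chain
        raise ValueError("no ligand selector set (ligand_resname or ligand_chain)")

    def ligand_atoms(self, heavy_only: bool = True) -> list[Atom]:
        return [a for a in self.atoms
                if self._is_ligand(a) and not (heavy_only and a.is_hydrogen)]

    def protein_atoms(self, heavy_only: bool = True) -> list[Atom]:
        return [a for a in self.atoms
                if not self._is_ligand(a) and not (heavy_only and a.is_hydrogen)]


def parse_structure(pdb_text: str, ligand_resname: str | None = None,
                    ligand_chain: str | None = None) -> StructureModel:
    """Parse PDB-format text into a :class:`StructureModel` (coordinates nm).

    Angstrom coordinates are converted to nm.  Elements come from the PDB
    element columns with an atom-name fallback (both handled by Bio.PDB's
    permissive parser, which also skips malformed records with a warning).
    Only the first model of a multi-model file is used.
    """
    parser = PDBParser(QUIET=True, PERMISSIVE=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", PDBConstructionWarning)
        structure = parser.get_structure("model", io.StringIO(pdb_text))
    atoms: list[Atom] = []
    models = list(structure)
    if not models:
        raise ValueError("no parseable ATOM/HETATM records")
    for chain in models[0]:
        for residue in chain:
            for atom in residue:
                element = (atom.element or "").strip().upper() or "X"
                # PDB prints 3 decimals in Angstrom; round away float32
                # noise so 3.800 A parses to exactly 0.38 nm
                x, y, z = (round(float(c), 3) / 10.0 for c in atom.coord)
                atoms.append(Atom(serial=atom.serial_number or 0,
                                  element=element,
                                  name=atom.get_name(),
                                  residue_name=residue.get_resname().strip(),
                                  residue_number=residue.id[1],
                                  chain=chain.id,
                                  xyz=(x, y, z)))
    if not atoms:
        raise ValueError("no parseable ATOM/HETATM records")
    if not all(np.isfinite(np.array([a.xyz for a in atoms])).ravel()):
        raise ValueError("non-finite coordinates in structure")
    return StructureModel(atoms=atoms, ligand_resname=ligand_resname,
                          ligand_chain=ligand_chain)


def parse_structure_file(path, **kwargs) -> StructureModel:
    with open(path) as fh:
        return parse_structure(fh.read(), **kwargs)


# ---------------------------------------------------------------------------
# Contact mapping

@dataclass(frozen=True)
class ResidueContact:
    chain: str
    residue_number: int
    residue_name: str
    min_distance_nm: float
    classes: frozenset[str] = frozenset()

    @property
    def residue_id(self) -> str:
        return f"{self.residue_name}{self.residue_number}"


@dataclass
class ContactReport:
    cutoff_nm: float
    records: list[ResidueContact] = field(default_factory=list)

    def residue_ids(self) -> set[tuple[str, int]]:
        return {(r.chain, r.residue_number) for r in self.records}

    def to_tsv(self) -> str:
        lines = ["residue\tchain\tmin_distance_nm\tclasses"]
        for r in self.records:
            lines.append(f"{r.residue_id}\t{r.chain}\t{r.min_distance_nm:.4f}\t"
                         + ",".join(sorted(r.classes)))
        return "\n".join(lines) + "\n"

    def to_text(self) -> str:
        """Human-readable residue listing, nearest first."""
        if not self.records:
            return f"No residues within {self.cutoff_nm} nm of the ligand.\n"
        lines = [f"Residues within {self.cutoff_nm} nm of the ligand "
                 "(nearest first):"]
        for r in self.records:
            cls = ", ".join(sorted(r.classes)) if r.classes else "unclassified"
            lines.append(f"  {r.residue_id:>8s} (chain {r.chain}) "
                         f"min {r.min_distance_nm:.3f} nm  [{cls}]")
        return "\n".join(lines) + "\n"


def _distance_matrix(a: Sequence[Atom], b: Sequence[Atom]) -> np.ndarray:
    if not a or not b:
        return np.empty((len(a), len(b)))
    pa = np.array([x.xyz for x in a])
    pb = np.array([x.xyz for x in b])
    return np.linalg.norm(pa[:, None, :] - pb[None, :, :], axis=-1)


def contact_residues(structure: StructureModel,
                     cutoff: float = CONTACT_CUTOFF_NM) -> ContactReport:
    """Residues with any heavy-atom pair closer than ``cutoff`` (strict <).

    The report is sorted by minimum ligand-residue distance.
    """
    ligand = structure.ligand_atoms()
    protein = structure.protein_atoms()
    if not ligand:
        raise ValueError("no ligand heavy atoms selected")
    if not protein:
        raise ValueError("no protein heavy atoms present")
    dist = _distance_matrix(ligand, protein)
    min_by_residue: dict[tuple[str, int, str], float] = {}
    per_atom_min = dist.min(axis=0)
    for atom, d in zip(protein, per_atom_min):
        key = (atom.chain, atom.residue_number, atom.residue_name)
        if d < min_by_residue.get(key, np.inf):
            min_by_residue[key] = float(d)
    records = [ResidueContact(chain=c, residue_number=n, residue_name=rn,
                              min_distance_nm=d)
               for (c, n, rn), d in min_by_residue.items() if d < cutoff]
    records.sort(key=lambda r: r.min_distance_nm)
    return ContactReport(cutoff_nm=cutoff, records=records)


def _ligand_aliphatic_carbons(structure: StructureModel) -> list[Atom]:
    """Ligand carbons with no covalently bonded O/N (distance < 0.17 nm)."""
    ligand = structure.ligand_atoms()
    carbons = [a for a in ligand if a.element == "C"]
    polar = [a for a in ligand if a.element in POLAR_ELEMENTS]
    if not polar or not carbons:
        return carbons
    dist = _distance_matrix(carbons, polar)
    return [c for c, row in zip(carbons, dist) if row.min() >= _BOND_CUTOFF_NM]


def classify_contacts(structure: StructureModel,
                      report: ContactReport) -> ContactReport:
    """Assign interaction classes to every residue of a contact report.

    Distance windows are closed on both ends; a residue may carry several
    classes; residues matching no specific class are tagged other_polar.
    """
    ligand = structure.ligand_atoms()
    aliphatic = _ligand_aliphatic_carbons(structure)
    protein = structure.protein_atoms()
    by_residue: dict[tuple[str, int], list[Atom]] = {}
    for atom in protein:
        by_residue.setdefault((atom.chain, atom.residue_number), []).append(atom)

    new_records = []
    for rec in report.records:
        res_atoms = by_residue[(rec.chain, rec.residue_number)]
        classes: set[str] = set()
        dist = _distance_matrix(ligand, res_atoms)
        for i, latom in enumerate(ligand):
            for j, ratom in enumerate(res_atoms):
                d = dist[i, j]
                if (latom.element in POLAR_ELEMENTS
                        and ratom.element in POLAR_ELEMENTS
                        and HBOND_WINDOW_NM[0] <= d <= HBOND_WINDOW_NM[1]):
                    classes.add("hydrogen_bond")
                if (latom.element == "C" and ratom.element == "C"
                        and CC_WINDOW_NM[0] <= d <= CC_WINDOW_NM[1]):
                    classes.add("nonpolar_CC")
        ring_atoms = AROMATIC_RING_ATOMS.get(rec.residue_name, frozenset())
        if ring_atoms and aliphatic:
            ring = [a for a in res_atoms if a.name in ring_atoms]
            if ring:
                d_ring = _distance_matrix(aliphatic, ring)
                if d_ring.min() < report.cutoff_nm:
                    classes.add("CH_pi")
        if not classes:
            classes.add("other_polar")
        new_records.append(replace(rec, classes=frozenset(classes)))
    return ContactReport(cutoff_nm=report.cutoff_nm, records=new_records)


def analyze_contacts(structure: StructureModel,
                     cutoff: float = CONTACT_CUTOFF_NM) -> ContactReport:
    """Convenience: contact mapping followed by classification."""
    return classify_contacts(structure, contact_residues(structure, cutoff))
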