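"""Reading, writing and atom selection for channel coordinate files.

Thin wrapper over :mod:`gemmi` that exposes a flat, author-numbered atom
model (:class:`StructureModel`) and the one selection the geometry stage
needs: the five symmetry-related constriction atoms of a residue ring
(:func:`select_ring`).

Conventions
-----------
* Author chain ids and residue numbers are preserved (the literature cites
  author numbers, e.g. I180, V205).
* Coordinates are in Angstrom, as stored; nothing is re-oriented on read.
* Of NMR-style multi-model files only the first model is used.
* Alternate locations are retained on read; selections resolve them to the
  highest-occupancy conformer (ties broken in favour of altloc 'A').
* Waters and ligands are retained in the model but never selected as
  constriction-ring residues.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import gemmi
import numpy as np

from .exceptions import (
    AmbiguousChainsError,
    EmptyStructureError,
    FormatError,
    IncompleteRingError,
    MissingAtomError,
)
from .pore_geometry import (
    ConstrictionRing,
    GeometryConstants,
    place_aromatic_hydrogens,
)

_WATER_NAMES = {"HOH", "WAT", "DOD"}
_PHE_RING_ATOMS = ("CG", "CD1", "CD2", "CE1", "CE2", "CZ")


@dataclass(frozen=True)
class Atom:
    """One coordinate record (ATOM or HETATM)."""

    chain_id: str
    residue_number: int
    residue_name: str
    atom_name: str
    alt_loc: str
    element: str
    position: np.ndarray  # (3,) A
    occupancy: float = 1.0
    het: bool = False

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise FormatError(
                f"atom {self.atom_name} {self.chain_id}/{self.residue_number}: "
                "position must be a finite 3-vector"
            )
        object.__setattr__(self, "position", pos)


@dataclass
class StructureModel:
    """Parsed atomic coordinates of a (pseudo-)pentameric channel."""

    identifier: str
    atoms: list[Atom] = field(default_factory=list)

    @property
    def chain_ids(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for a in self.atoms:
            seen.setdefault(a.chain_id, None)
        return tuple(seen)

    def iter_atoms(self, resolve_altloc: bool = False) -> Iterator[Atom]:
        """All atoms; with ``resolve_altloc`` only one conformer per atom.

        The kept conformer is the highest-occupancy one; on a tie the
        lexicographically smallest altloc wins, so 'A' beats 'B'.
        """
        if not resolve_altloc:
            yield from self.atoms
            return
        best: dict[tuple[str, int, str, str], Atom] = {}
        order: list[tuple[str, int, str, str]] = []
        for a in self.atoms:
            key = (a.chain_id, a.residue_number, a.residue_name, a.atom_name)
            cur = best.get(key)
            if cur is None:
                best[key] = a
                order.append(key)
            elif (a.occupancy, _altloc_rank(a.alt_loc)) > (
                cur.occupancy,
                _altloc_rank(cur.alt_loc),
            ):
                best[key] = a
        for key in order:
            yield best[key]

    def residue_atoms(self, chain_id: str, residue_number: int) -> dict[str, Atom]:
        """Altloc-resolved atoms of one residue, keyed by atom name."""
        return {
            a.atom_name: a
            for a in self.iter_atoms(resolve_altloc=True)
            if a.chain_id == chain_id and a.residue_number == residue_number
        }


def _altloc_rank(alt: str) -> float:
    # empty altloc outranks 'A'; otherwise later letters rank lower
    if alt == "":
        return 0.0
    return -ord(alt[0])


# ---------------------------------------------------------------------------
# read / write
# ---------------------------------------------------------------------------

_FORMATS = {
    "pdb": gemmi.CoorFormat.Pdb,
    "mmcif": gemmi.CoorFormat.Mmcif,
    "auto": gemmi.CoorFormat.Detect,
}


def read_structure(path: str | os.PathLike, format: str = "auto") -> StructureModel:
    """Read a PDB or mmCIF file into a :class:`StructureModel`.

    All ATOM/HETATM records of the first model are returned, with author
    chain ids and residue numbering preserved and alternate locations
    retained.
    """
    path = Path(path)
    if format not in _FORMATS:
        raise ValueError(f"format must be one of {sorted(_FORMATS)}, got {format!r}")
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        st = gemmi.read_structure(str(path), format=_FORMATS[format])
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"{path.name}: {exc}") from exc

    atoms: list[Atom] = []
    if len(st) > 0:
        model = st[0]
        for chain in model:
            for residue in chain:
                het = residue.het_flag == "H" or residue.name in _WATER_NAMES
                for atom in residue:
                    atoms.append(
                        Atom(
                            chain_id=chain.name,
                            residue_number=residue.seqid.num,
                            residue_name=residue.name,
                            atom_name=atom.name,
                            alt_loc=atom.altloc if atom.altloc != "\0" else "",
                            element=atom.element.name,
                            position=np.array(
                                [atom.pos.x, atom.pos.y, atom.pos.z]
                            ),
                            occupancy=atom.occ,
                            het=het,
                        )
                    )
    if not atoms:
        raise EmptyStructureError(f"{path.name}: no atoms in file")
    identifier = st.name if st.name else path.stem
    return StructureModel(identifier=identifier, atoms=atoms)


def _to_gemmi(model: StructureModel) -> gemmi.Structure:
    # gemmi containers copy on add_*, so build each level fully first
    grouped: dict[str, dict[tuple[int, str], list[Atom]]] = {}
    for a in model.atoms:
        grouped.setdefault(a.chain_id, {}).setdefault(
            (a.residue_number, a.residue_name), []
        ).append(a)

    st = gemmi.Structure()
    st.name = model.identifier
    gmodel = gemmi.Model(1)
    for chain_id, res_groups in grouped.items():
        chain = gemmi.Chain(chain_id)
        for (resnum, resname), res_atoms in res_groups.items():
            res = gemmi.Residue()
            res.name = resname
            res.seqid = gemmi.SeqId(resnum, " ")
            res.het_flag = "H" if res_atoms[0].het else "A"
            for a in res_atoms:
                gatom = gemmi.Atom()
                gatom.name = a.atom_name
                gatom.pos = gemmi.Position(*a.position)
                gatom.occ = a.occupancy
                gatom.element = gemmi.Element(a.element)
                if a.alt_loc:
                    gatom.altloc = a.alt_loc
                res.add_atom(gatom)
            chain.add_residue(res)
        gmodel.add_chain(chain)
    st.add_model(gmodel)
    return st


def write_structure(model: StructureModel, path: str | os.PathLike) -> None:
    """Write a :class:`StructureModel` to PDB (default) or mmCIF text.

    The output format follows the file extension: ``.cif`` writes mmCIF,
    anything else writes fixed-column PDB v3.3.  Chain ids longer than one
    character cannot be represented in PDB columns; writing such a model to
    a ``.pdb`` path raises :class:`FormatError` (use mmCIF instead).
    Coordinates survive a PDB round trip to 0.001 A.
    """
    if not model.atoms:
        raise EmptyStructureError("refusing to write an empty structure")
    path = Path(path)
    as_cif = path.suffix.lower() == ".cif"
    if not as_cif:
        long_chains = sorted({a.chain_id for a in model.atoms if len(a.chain_id) > 1})
        if long_chains:
            raise FormatError(
                f"chain ids {long_chains} do not fit the one-character PDB "
                "chain column; write an mmCIF file (.cif) instead"
            )
    st = _to_gemmi(model)
    try:
        if as_cif:
            st.setup_entities()
            st.make_mmcif_document().write_file(str(path))
        else:
            st.write_pdb(str(path))
    except OSError as exc:
        raise OSError(f"cannot write {path}: {exc}") from exc


def load_deposited(
    pdb_id: str, directory: str | os.PathLike = "data/deposited"
) -> StructureModel:
    """Load a deposited PDB entry from a local mirror directory.

    Looks for ``<id>.pdb``, ``pdb<id>.ent`` or ``<id>.cif`` (lower case)
    under ``directory``.  This package does not download coordinates;
    deposited entries must be fetched separately and placed there.
    """
    directory = Path(directory)
    pid = pdb_id.lower()
    for name in (f"{pid}.pdb", f"pdb{pid}.ent", f"{pid}.cif"):
        candidate = directory / name
        if candidate.exists():
            m = read_structure(candidate)
            m.identifier = pdb_id.upper()
            return m
    raise FileNotFoundError(
        f"deposited entry {pdb_id.upper()} not found under {directory}/ "
        f"(expected {pid}.pdb, pdb{pid}.ent or {pid}.cif); download it from "
        "the Protein Data Bank and place it there"
    )


# ---------------------------------------------------------------------------
# ring selection
# ---------------------------------------------------------------------------

def select_ring(
    model: StructureModel,
    residue_number: int,
    atom_rule: str = "auto",
    chains: Iterable[str] | None = None,
    constants: GeometryConstants | None = None,
) -> ConstrictionRing:
    """Select the five constriction atoms of a residue ring.

    Under the ``"auto"`` rule the probe atom is chosen by residue type:

    * Ile: the CD1 methyl carbon (probe vdW radius 2.00 A);
    * Val / Leu: whichever of the two terminal methyl carbons lies nearer
      the five-chain ring centroid, i.e. the pore-lining methyl (2.00 A);
    * Phe: an ideal aromatic hydrogen is inferred for each ring carbon and
      the one nearest the ring centroid is used (1.20 A).

    Any other value of ``atom_rule`` is taken as an explicit atom name; the
    probe radius is then 1.20 A for hydrogens and 2.00 A otherwise.
    Exactly five chains must carry the residue: fewer raises
    :class:`IncompleteRingError`, more raises :class:`AmbiguousChainsError`
    unless an explicit five-chain list is given.
    """
    constants = constants or GeometryConstants()

    present: dict[str, dict[str, Atom]] = {}
    for cid in model.chain_ids:
        ratoms = {
            name: a
            for name, a in model.residue_atoms(cid, residue_number).items()
            if not a.het
        }
        if ratoms:
            present[cid] = ratoms

    if chains is not None:
        wanted = list(chains)
        missing = [c for c in wanted if c not in present]
        if missing:
            raise IncompleteRingError(
                f"residue {residue_number} absent from requested chain(s) "
                f"{missing}"
            )
        present = {c: present[c] for c in wanted}

    if len(present) > 5:
        raise AmbiguousChainsError(
            f"residue {residue_number} present in {len(present)} chains "
            f"({sorted(present)}); pass an explicit five-chain list"
        )
    if len(present) < 5:
        missing = sorted(set(model.chain_ids) - set(present))
        raise IncompleteRingError(
            f"residue {residue_number} present in only {len(present)} chain(s); "
            f"missing from {missing}"
        )

    # deterministic chain order regardless of file order
    order = sorted(present)
    res_names = {present[c][next(iter(present[c]))].residue_name for c in order}
    residue_name = sorted(res_names)[0]

    if atom_rule == "auto":
        if residue_name == "ILE":
            return _explicit_ring(
                present, order, residue_number, residue_name, "CD1",
                constants.methyl_vdw,
            )
        if residue_name in ("VAL", "LEU"):
            candidates = ("CG1", "CG2") if residue_name == "VAL" else ("CD1", "CD2")
            return _nearest_methyl_ring(
                present, order, residue_number, residue_name, candidates,
                constants.methyl_vdw,
            )
        if residue_name == "PHE":
            return _phe_hydrogen_ring(
                present, order, residue_number, residue_name, constants
            )
        raise MissingAtomError(
            f"auto probe rule is defined for ILE/VAL/LEU/PHE only; residue "
            f"{residue_number} is {residue_name} - give an explicit atom name"
        )

    # explicit atom name
    first = present[order[0]].get(atom_rule)
    is_h = first is not None and first.element.upper() == "H"
    probe = constants.hydrogen_vdw if is_h else constants.methyl_vdw
    return _explicit_ring(
        present, order, residue_number, residue_name, atom_rule, probe
    )


def _explicit_ring(present, order, residue_number, residue_name, atom_name, probe):
    points = []
    missing = []
    for cid in order:
        atom = present[cid].get(atom_name)
        if atom is None:
            missing.append(cid)
        else:
            points.append(atom.position)
    if missing:
        raise MissingAtomError(
            f"atom {atom_name} missing from residue {residue_number} "
            f"in chain(s) {missing}"
        )
    return ConstrictionRing(
        residue_number=residue_number,
        residue_name=residue_name,
        atom_name=atom_name,
        points=np.array(points),
        probe_vdw_radius=probe,
    )


def _nearest_methyl_ring(present, order, residue_number, residue_name,
                         candidates, probe):
    pools: dict[str, list[Atom]] = {}
    for cid in order:
        avail = [present[cid][n] for n in candidates if n in present[cid]]
        if not avail:
            raise MissingAtomError(
                f"residue {residue_number} ({residue_name}) in chain {cid} "
                f"has none of the methyl carbons {candidates}"
            )
        pools[cid] = avail
    all_pos = np.array([a.position for pool in pools.values() for a in pool])
    centroid = all_pos.mean(axis=0)
    points = []
    names = []
    for cid in order:
        dists = [np.linalg.norm(a.position - centroid) for a in pools[cid]]
        chosen = pools[cid][int(np.argmin(dists))]
        points.append(chosen.position)
        names.append(chosen.atom_name)
    # label with the majority choice (usually all five agree)
    label = max(set(names), key=names.count)
    return ConstrictionRing(
        residue_number=residue_number,
        residue_name=residue_name,
        atom_name=label,
        points=np.array(points),
        probe_vdw_radius=probe,
    )


def _phe_hydrogen_ring(present, order, residue_number, residue_name, constants):
    carbons: dict[str, np.ndarray] = {}
    for cid in order:
        missing = [n for n in _PHE_RING_ATOMS if n not in present[cid]]
        if missing:
            raise MissingAtomError(
                f"PHE {residue_number} in chain {cid} is missing ring "
                f"carbon(s) {missing}"
            )
        carbons[cid] = np.array(
            [present[cid][n].position for n in _PHE_RING_ATOMS]
        )
    chosen = place_aromatic_hydrogens(
        carbons, bond_length=constants.aromatic_CH_bond
    )
    return ConstrictionRing(
        residue_number=residue_number,
        residue_name=residue_name,
        atom_name="H_arom",
        points=np.array([chosen[cid] for cid in order]),
        probe_vdw_radius=constants.hydrogen_vdw,
    )
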