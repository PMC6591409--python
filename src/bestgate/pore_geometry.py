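"""Constriction-ring geometry of pentameric bestrophin channels.

The narrow points of the bestrophin ion-conducting pathway (the "neck" and
the "aperture") are rings of five symmetry-related side-chain atoms, one per
protomer.  The effective pore radius of such a ring is obtained from the
five adjacent-neighbour (pentagon edge) distances a1..a5 between the probe
atoms:

    radius = mean(a1..a5) / 1.17  -  r_vdw(probe)

where 1.17 approximates 2*sin(36 deg) = 1.1756, the edge/circumradius ratio
of a regular pentagon, and r_vdw is 2.00 A for a united-atom methyl carbon
(Ile/Val/Leu) or 1.20 A for an aromatic hydrogen (Phe).  The divisor maps
the mean edge length onto the circumradius of the ring; subtracting the
probe van der Waals radius leaves the free radius seen by a permeating ion.

This module also quantifies ring asymmetry (relevant to "breathing" of the
aperture), infers aromatic hydrogens for Phe rings, classifies which anions
fit through a constriction of given radius, and superposes structures to
report RMSD.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable, Mapping, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .exceptions import (
    GeometryError,
    InsufficientOverlapError,
    MissingAtomError,
)

if TYPE_CHECKING:  # pragma: no cover
    from .structure_io import StructureModel

logger = logging.getLogger(__name__)

#: Edge/circumradius ratio of a regular pentagon, 2*sin(36 deg).
PENTAGON_FACTOR_EXACT = 2.0 * math.sin(math.radians(36.0))


@dataclass(frozen=True)
class GeometryConstants:
    """Fixed constants of the ring-radius formula.

    ``pentagon_factor`` defaults to the rounded value 1.17 used when the
    printed radii were derived; :meth:`exact` gives 2*sin(36 deg) instead.
    """

    pentagon_factor: float = 1.17
    methyl_vdw: float = 2.00      # A, united-atom CH3
    hydrogen_vdw: float = 1.20    # A, aromatic H
    aromatic_CH_bond: float = 1.08  # A, ideal aromatic C-H

    @classmethod
    def exact(cls) -> "GeometryConstants":
        """Constants with the exact pentagon edge/circumradius ratio."""
        return cls(pentagon_factor=PENTAGON_FACTOR_EXACT)


@dataclass(frozen=True)
class ConstrictionRing:
    """Five symmetry-related probe atoms of one constriction residue ring."""

    residue_number: int
    residue_name: str
    atom_name: str
    points: np.ndarray          # (5, 3) A
    probe_vdw_radius: float     # A

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.shape != (5, 3):
            raise GeometryError(
                f"a constriction ring needs exactly 5 points, got {pts.shape}"
            )
        if not np.all(np.isfinite(pts)):
            raise GeometryError("ring points must be finite")
        object.__setattr__(self, "points", pts)

    @property
    def centroid(self) -> np.ndarray:
        return self.points.mean(axis=0)


@dataclass(frozen=True)
class IonTable:
    """Dehydrated and hydrated anion radii (A) used for permeant sizing."""

    dehydrated: Mapping[str, float] = field(
        default_factory=lambda: {
            "Cl-": 1.8,
            "Br-": 2.0,
            "I-": 2.2,
            "SCN-": 2.2,
            "CH3SO3-": 2.6,
        }
    )
    hydrated: Mapping[str, float] = field(
        default_factory=lambda: {"Cl-": 3.3, "Br-": 3.3, "I-": 3.3}
    )


@dataclass(frozen=True)
class RingAsymmetry:
    """Spread of the five probe atoms around their common centroid."""

    per_point_centroid_distances: np.ndarray  # (5,) A
    spread: float                              # max - min, A
    cv: float                                  # dimensionless


@dataclass(frozen=True)
class PermeantClassification:
    passes_dehydrated: tuple[str, ...]
    passes_hydrated: tuple[str, ...]


@dataclass
class RingRecord:
    """One row of a pore report."""

    residue_number: int
    residue_name: str | None = None
    atom_name: str | None = None
    radius: float | None = None
    asymmetry_spread: float | None = None
    asymmetry_cv: float | None = None
    passes_dehydrated: tuple[str, ...] = ()
    passes_hydrated: tuple[str, ...] = ()
    error: str | None = None


@dataclass
class PoreReport:
    """Per-structure summary of constriction radii and ion accommodation."""

    structure_id: str
    records: list[RingRecord]
    rmsd_vs_reference: float | None = None
    reference_id: str | None = None

    def to_dict(self) -> dict:
        recs = []
        for r in self.records:
            recs.append(
                {
                    "residue_number": r.residue_number,
                    "residue_name": r.residue_name,
                    "atom_name": r.atom_name,
                    "radius_A": r.radius,
                    "asymmetry_spread_A": r.asymmetry_spread,
                    "asymmetry_cv": r.asymmetry_cv,
                    "passes_dehydrated": list(r.passes_dehydrated),
                    "passes_hydrated": list(r.passes_hydrated),
                    "error": r.error,
                }
            )
        return {
            "structure_id": self.structure_id,
            "rings": recs,
            "rmsd_vs_reference_A": self.rmsd_vs_reference,
            "reference_id": self.reference_id,
        }

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(self.to_dict()["rings"])


# ---------------------------------------------------------------------------
# ring plane / adjacency helpers
# ---------------------------------------------------------------------------

def _ring_plane_basis(points: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Best-fit plane of a point set: (e1, e2, normal), via SVD."""
    centered = points - points.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    return vt[0], vt[1], vt[2]


def _angular_order(points: np.ndarray) -> np.ndarray:
    """Indices of the points in angular order about their centroid.

    Angles are measured in the best-fit plane; ties (coincident projections)
    are broken by distance from the centroid, then by index.
    """
    centroid = points.mean(axis=0)
    e1, e2, _ = _ring_plane_basis(points)
    rel = points - centroid
    theta = np.arctan2(rel @ e2, rel @ e1)
    dist = np.linalg.norm(rel, axis=1)
    return np.lexsort((np.arange(len(points)), dist, theta))


def pentagon_edges(points: np.ndarray) -> np.ndarray:
    """The five adjacent-neighbour distances a1..a5 of a five-point ring.

    Adjacency is recovered geometrically (angular order about the centroid
    in the best-fit ring plane), so the result does not depend on the order
    in which the chains were stored.
    """
    pts = np.asarray(points, dtype=float)
    order = _angular_order(pts)
    ordered = pts[order]
    return np.linalg.norm(ordered - np.roll(ordered, -1, axis=0), axis=1)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def ring_radius(
    ring: ConstrictionRing, constants: GeometryConstants | None = None
) -> float:
    """Constriction radius (A) of a five-atom ring.

    Mean pentagon-edge distance divided by the pentagon factor, minus the
    probe van der Waals radius.  Overclosed rings yield negative radii,
    which are reported as-is.
    """
    constants = constants or GeometryConstants()
    pts = ring.points
    # coincident points make the adjacency (and the ring itself) meaningless
    diffs = pts[:, None, :] - pts[None, :, :]
    pd2 = np.linalg.norm(diffs, axis=-1)
    if np.any(pd2[np.triu_indices(5, k=1)] < 1e-8):
        raise GeometryError(
            f"ring at residue {ring.residue_number} has coincident points"
        )
    edges = pentagon_edges(pts)
    return float(edges.mean() / constants.pentagon_factor - ring.probe_vdw_radius)


def ring_asymmetry(ring: ConstrictionRing) -> RingAsymmetry:
    """Per-point centroid distances, their spread (max-min) and CV."""
    d = np.linalg.norm(ring.points - ring.centroid, axis=1)
    mean = d.mean()
    cv = float(d.std() / mean) if mean > 0 else 0.0
    return RingAsymmetry(
        per_point_centroid_distances=d,
        spread=float(d.max() - d.min()),
        cv=cv,
    )


def aromatic_hydrogens(
    ring_carbons: np.ndarray, bond_length: float = 1.08
) -> np.ndarray:
    """Ideal in-plane hydrogen positions for one six-carbon aromatic ring.

    Ring connectivity is inferred from inter-carbon distances; each hydrogen
    is placed along its carbon's exocyclic bisector (away from the midpoint
    of the two ring neighbours), projected into the best-fit ring plane, at
    the given C-H bond length.

    Parameters
    ----------
    ring_carbons:
        (6, 3) positions of the ring carbons, in any order.

    Returns
    -------
    (6, 3) hydrogen positions, one per input carbon, same order.
    """
    c = np.asarray(ring_carbons, dtype=float)
    if c.shape != (6, 3):
        raise MissingAtomError(
            f"an aromatic ring needs six carbons, got shape {c.shape}"
        )
    # neighbours = two nearest ring carbons
    d = np.linalg.norm(c[:, None, :] - c[None, :, :], axis=-1)
    np.fill_diagonal(d, np.inf)
    nbrs = np.argsort(d, axis=1)[:, :2]
    _, _, normal = _ring_plane_basis(c)
    h = np.empty_like(c)
    for i in range(6):
        mid = c[nbrs[i]].mean(axis=0)
        direction = c[i] - mid
        direction -= (direction @ normal) * normal  # keep in-plane
        norm = np.linalg.norm(direction)
        if norm < 1e-9:
            raise GeometryError("degenerate aromatic ring geometry")
        h[i] = c[i] + bond_length * direction / norm
    return h


def place_aromatic_hydrogens(
    phe_ring_atoms: Mapping[str, np.ndarray],
    bond_length: float = 1.08,
) -> dict[str, np.ndarray]:
    """Per chain, the inferred Phe-ring hydrogen nearest the pore axis.

    Parameters
    ----------
    phe_ring_atoms:
        Mapping ``chain_id -> (6, 3)`` ring-carbon positions.

    Returns
    -------
    Mapping ``chain_id ->`` chosen hydrogen position.  "Nearest" is judged
    against the centroid of all ring carbons of all chains, which sits on
    the (approximate) five-fold axis.
    """
    all_c = np.concatenate([np.asarray(v, float) for v in phe_ring_atoms.values()])
    pore_centroid = all_c.mean(axis=0)
    chosen: dict[str, np.ndarray] = {}
    for chain, carbons in phe_ring_atoms.items():
        hs = aromatic_hydrogens(carbons, bond_length=bond_length)
        dist = np.linalg.norm(hs - pore_centroid, axis=1)
        chosen[chain] = hs[int(np.argmin(dist))]
    return chosen


def classify_permeants(
    radius: float, ion_table: IonTable | None = None
) -> PermeantClassification:
    """Which anions fit through a constriction of the given radius.

    An ion passes iff its radius is <= the pore radius (inclusive: a 2.6 A
    pore passes the 2.6 A dehydrated methanesulfonate).  A negative pore
    radius passes nothing and logs a warning.
    """
    table = ion_table or IonTable()
    if radius < 0:
        logger.warning(
            "negative pore radius %.3f A: no ion passes (overclosed ring)", radius
        )
        return PermeantClassification((), ())
    deh = tuple(ion for ion, r in table.dehydrated.items() if r <= radius)
    hyd = tuple(ion for ion, r in table.hydrated.items() if r <= radius)
    return PermeantClassification(deh, hyd)


def _selection_positions(
    model: "StructureModel", selection: str
) -> dict[tuple[str, int, str], np.ndarray]:
    out: dict[tuple[str, int, str], np.ndarray] = {}
    for atom in model.iter_atoms(resolve_altloc=True):
        if selection == "CA":
            if atom.atom_name != "CA":
                continue
        elif selection == "all-heavy":
            if atom.element.upper() == "H":
                continue
        else:
            raise ValueError(f"unknown selection {selection!r}")
        out[(atom.chain_id, atom.residue_number, atom.atom_name)] = atom.position
    return out


def superpose_rmsd(
    model_a: "StructureModel",
    model_b: "StructureModel",
    selection: str = "CA",
) -> float:
    """RMSD (A) after optimal rigid (reflection-free) superposition.

    Atoms are paired by ``(chain_id, residue_number, atom_name)``;
    ``selection`` is ``"CA"`` (default) or ``"all-heavy"``.  The rotation is
    the Kabsch least-squares solution.
    """
    pos_a = _selection_positions(model_a, selection)
    pos_b = _selection_positions(model_b, selection)
    keys = sorted(pos_a.keys() & pos_b.keys())
    if len(keys) < 3:
        raise InsufficientOverlapError(
            f"only {len(keys)} matched atoms between "
            f"{model_a.identifier!r} and {model_b.identifier!r} (need >= 3)"
        )
    a = np.array([pos_a[k] for k in keys])
    b = np.array([pos_b[k] for k in keys])
    a_c = a - a.mean(axis=0)
    b_c = b - b.mean(axis=0)
    _, rssd = Rotation.align_vectors(a_c, b_c)
    return float(rssd / math.sqrt(len(keys)))


def pore_profile(
    model: "StructureModel",
    residues: Sequence[int | tuple[int, str]],
    reference: "StructureModel | None" = None,
    constants: GeometryConstants | None = None,
    ion_table: IonTable | None = None,
    chains: Iterable[str] | None = None,
) -> PoreReport:
    """Batch constriction report for a structure.

    Each entry of ``residues`` is an author residue number, or a
    ``(residue_number, atom_name)`` pair to override the automatic probe
    rule.  Per-residue failures are recorded in the report instead of
    aborting the batch.  Records are ordered by residue number.
    """
    from .structure_io import select_ring  # local import to avoid a cycle

    constants = constants or GeometryConstants()
    specs: list[tuple[int, str | None]] = []
    for spec in residues:
        if isinstance(spec, tuple):
            specs.append((int(spec[0]), spec[1]))
        else:
            specs.append((int(spec), None))
    specs.sort(key=lambda s: s[0])

    records: list[RingRecord] = []
    for resnum, atom_name in specs:
        rec = RingRecord(residue_number=resnum)
        try:
            ring = select_ring(
                model,
                resnum,
                atom_rule="auto" if atom_name is None else atom_name,
                chains=chains,
                constants=constants,
            )
            rec.residue_name = ring.residue_name
            rec.atom_name = ring.atom_name
            rec.radius = ring_radius(ring, constants)
            asym = ring_asymmetry(ring)
            rec.asymmetry_spread = asym.spread
            rec.asymmetry_cv = asym.cv
            cls = classify_permeants(rec.radius, ion_table)
            rec.passes_dehydrated = cls.passes_dehydrated
            rec.passes_hydrated = cls.passes_hydrated
        except Exception as exc:  # recorded, not raised
            rec.error = f"{type(exc).__name__}: {exc}"
        records.append(rec)

    rmsd = None
    ref_id = None
    if reference is not None:
        rmsd = superpose_rmsd(model, reference, selection="CA")
        ref_id = reference.identifier
    return PoreReport(
        structure_id=model.identifier,
        records=records,
        rmsd_vs_reference=rmsd,
        reference_id=ref_id,
    )
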