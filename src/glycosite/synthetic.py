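"""Toy protein-ligand complexes with interface labels known by construction.

Real curated complexes require bulk downloads; these generated fixtures are
first-class test data.  A toy complex is a single protein chain laid out on
a jittered lattice plus a cluster of ligand atoms placed so that a chosen
set of residues is in contact (within ``contact_distance`` of a ligand atom)
and every other residue is strictly farther than ``cutoff + 2`` Å from all
ligand atoms.  Ground-truth labels are therefore exact by construction and
independent of any distance-scan code.

Residue atoms use generic backbone-like elements (N, C, C, O); ligand atoms
alternate C and O and carry a residue code from the carbohydrate vocabulary
so the partitioning pipeline classifies them.  This is a deliberate
simplification: no sugar stereochemistry or glycosidic geometry is modelled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .structio import Atom, AtomicStructure, SubunitPartition, partition_subunits
from .structio import CarbVocabulary, DEFAULT_VOCAB

__all__ = ["ToyComplexConfig", "RigidTransform", "make_toy_complex", "random_rigid_transform"]

LABEL_CUTOFF = 4.0  # Å, the labeling cutoff the generator guarantees against
CLEARANCE = 2.0     # non-contact residues sit > cutoff + CLEARANCE from the ligand

_RESIDUE_ELEMENTS = ["N", "C", "C", "O"]
_RESIDUE_ATOM_NAMES = ["N", "CA", "C", "O"]
_PROTEIN_RESNAMES = [
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
]


@dataclass(frozen=True)
class ToyComplexConfig:
    n_residues: int = 10
    atoms_per_residue: int = 4
    n_ligand_atoms: int = 8
    contact_residues: frozenset[int] = frozenset({2, 3})
    contact_distance: float = 3.5   # Å, must be < LABEL_CUTOFF
    spacing: float = 6.0            # Å between residue centers
    ligand_resname: str = "GLC"     # any code from the carbohydrate vocabulary
    seed: int = 0

    def __post_init__(self):
        if not self.contact_distance < LABEL_CUTOFF:
            raise ValueError("contact_distance must be below the 4 Å labeling cutoff")
        if not set(self.contact_residues) <= set(range(self.n_residues)):
            raise ValueError("contact_residues out of range")


@dataclass(frozen=True)
class RigidTransform:
    """A proper rigid motion x -> R x + t."""

    rotation: np.ndarray    # 3x3, orthonormal, det +1
    translation: np.ndarray  # 3-vector, Å

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)


def make_toy_complex(
    config: ToyComplexConfig, vocab: CarbVocabulary | None = None
) -> tuple[AtomicStructure, SubunitPartition, np.ndarray]:
    """Generate one toy complex.

    Returns the structure, its subunit partition and the ground-truth
    per-residue contact labels (1 exactly on ``config.contact_residues``).
    Fully determined by ``config.seed``.
    """
    vocab = vocab or DEFAULT_VOCAB
    if config.ligand_resname not in vocab.carbohydrate_codes:
        raise ValueError(f"{config.ligand_resname!r} not in the carbohydrate vocabulary")
    rng = np.random.default_rng(config.seed)
    contacts = sorted(config.contact_residues)

    # residue centers along x with mild jitter; residues far (in chain
    # distance) from every contact residue bend away from the ligand side
    # (-y) so the non-contact clearance holds even at the default spacing
    centers = np.zeros((config.n_residues, 3))
    centers[:, 0] = np.arange(config.n_residues) * config.spacing
    if contacts:
        chain_dist = np.array(
            [min(abs(r - c) for c in contacts) for r in range(config.n_residues)]
        )
        centers[:, 1] = -3.0 * np.minimum(chain_dist, 3)
    centers += rng.uniform(-0.3, 0.3, size=centers.shape)
    local = np.array(
        [[0.0, 0.0, 0.0], [1.2, 0.0, 0.0], [0.0, 1.2, 0.0], [0.6, 0.6, 1.0]]
    )
    atoms: list[Atom] = []
    res_coords = []
    for r in range(config.n_residues):
        offsets = np.array(
            [local[i % 4] + rng.uniform(-0.15, 0.15, 3) for i in range(config.atoms_per_residue)]
        )
        coords_r = centers[r] + offsets
        res_coords.append(coords_r)
        resname = _PROTEIN_RESNAMES[rng.integers(0, len(_PROTEIN_RESNAMES))]
        for a in range(config.atoms_per_residue):
            atoms.append(
                Atom(
                    element=_RESIDUE_ELEMENTS[a % 4],
                    coords=tuple(coords_r[a]),
                    atom_name=_RESIDUE_ATOM_NAMES[a % 4] if a < 4 else f"C{a}",
                    residue_key=("A", r + 1, ""),
                    residue_name=resname,
                    is_polymer=True,
                )
            )

    # ligand atoms: one anchor exactly contact_distance above the topmost
    # atom of each contact residue, the rest clustered above the anchors
    if contacts:
        if config.n_ligand_atoms < len(contacts):
            raise ValueError("need at least one ligand atom per contact residue")
        anchors = []
        for r in contacts:
            top = res_coords[r][np.argmax(res_coords[r][:, 1])]
            anchors.append(top + np.array([0.0, config.contact_distance, 0.0]))
        anchors = np.array(anchors)
        lig = np.array([anchors[i % len(anchors)] for i in range(config.n_ligand_atoms)])
        n_extra = config.n_ligand_atoms - len(anchors)
        if n_extra > 0:
            lig[len(anchors):] += (
                rng.uniform(-0.4, 0.4, size=(n_extra, 3)) + np.array([0.0, 0.8, 0.0])
            )
    else:
        far = centers.max(axis=0) + np.array([0.0, 50.0, 0.0])
        lig = far + rng.uniform(-0.5, 0.5, size=(config.n_ligand_atoms, 3))
    lig = np.asarray(lig)

    # verify the geometric contract; refuse configs it cannot hold for
    labels = np.zeros(config.n_residues, dtype=np.int8)
    for r in range(config.n_residues):
        dmin = np.linalg.norm(res_coords[r][:, None, :] - lig[None, :, :], axis=-1).min()
        if r in config.contact_residues:
            if dmin > config.contact_distance + 1e-9:
                raise ValueError(f"residue {r} not placed within contact distance")
            labels[r] = 1
        elif dmin <= LABEL_CUTOFF + CLEARANCE:
            raise ValueError(
                f"residue {r} at {dmin:.2f} Å violates the non-contact clearance; "
                "increase spacing or reduce ligand size"
            )

    lig_elements = ["C", "O"]
    for i, pos in enumerate(lig):
        atoms.append(
            Atom(
                element=lig_elements[i % 2],
                coords=tuple(pos),
                atom_name=f"{lig_elements[i % 2]}{i + 1}",
                residue_key=("L:1", 1, ""),
                residue_name=config.ligand_resname,
                is_polymer=False,
            )
        )

    structure = AtomicStructure(atoms, source_id=f"toy{config.seed}")
    partition = partition_subunits(structure, vocab)
    return structure, partition, labels


def random_rigid_transform(seed: int) -> RigidTransform:
    """Draw a uniform random rotation (normalized quaternion) and a
    translation uniform in [-20, 20]^3 Å."""
    rng = np.random.default_rng(seed)
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    R = np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )
    t = rng.uniform(-20.0, 20.0, size=3)
    return RigidTransform(R, t)
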