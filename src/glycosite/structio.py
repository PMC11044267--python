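"""Structure input/output and preprocessing.

Reads protein (or protein-ligand) structures from PDB/mmCIF via gemmi and
produces a clean single-entity atomic structure: all models merged, waters
and hydrogens removed, alternate locations resolved to the highest-occupancy
conformer, and every discrete non-polymer molecule assigned its own unique
chain name.  The cleaned structure is then partitioned into typed subunits
(protein / carbohydrate / cyclodextrin / other) driven by a configurable
carbohydrate residue-code vocabulary.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np
import pandas as pd
import yaml

__all__ = [
    "Atom",
    "AtomicStructure",
    "Subunit",
    "SubunitPartition",
    "CarbVocabulary",
    "DEFAULT_VOCAB",
    "load_structure",
    "preprocess",
    "partition_subunits",
    "write_structure",
    "write_predictions",
    "StructureError",
]

WATER_NAMES = {"HOH", "DOD", "WAT"}
HYDROGEN_ELEMENTS = {"H", "D"}
# two non-polymer residues closer than this (heavy-atom min distance, Å) are
# treated as covalently linked, e.g. glycosidically bonded sugar rings
COVALENT_LINK_CUTOFF = 1.8


class StructureError(ValueError):
    """Raised for unreadable, malformed or degenerate structures."""


@dataclass(frozen=True)
class Atom:
    """One heavy atom of a cleaned structure."""

    element: str                      # uppercase element symbol, e.g. "C", "ZN"
    coords: tuple[float, float, float]  # Å
    atom_name: str
    residue_key: tuple[str, int, str]   # (chain id, residue number, insertion code)
    residue_name: str                   # chemical component code
    is_polymer: bool

    def __post_init__(self):
        if not self.element:
            raise StructureError("atom with empty element symbol")
        if not np.all(np.isfinite(self.coords)):
            raise StructureError("atom with non-finite coordinates")


@dataclass
class AtomicStructure:
    """An ordered collection of atoms forming one entity."""

    atoms: list[Atom]
    source_id: str = ""
    model_count_merged: int = 1

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        """(N, 3) float array of coordinates in Å."""
        return np.array([a.coords for a in self.atoms], dtype=np.float64)

    @property
    def elements(self) -> list[str]:
        return [a.element for a in self.atoms]

    def residues(self) -> list[tuple[tuple[str, int, str], str, list[int]]]:
        """Residues in atom order as (residue_key, residue_name, atom indices)."""
        out: list[tuple[tuple[str, int, str], str, list[int]]] = []
        index: dict[tuple[str, int, str], int] = {}
        for i, a in enumerate(self.atoms):
            if a.residue_key not in index:
                index[a.residue_key] = len(out)
                out.append((a.residue_key, a.residue_name, []))
            out[index[a.residue_key]][2].append(i)
        return out

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "AtomicStructure":
        """Return a copy with coordinates rigidly transformed (x -> Rx + t)."""
        R = np.asarray(rotation, dtype=np.float64)
        t = np.asarray(translation, dtype=np.float64)
        atoms = [
            Atom(
                a.element,
                tuple(R @ np.asarray(a.coords) + t),
                a.atom_name,
                a.residue_key,
                a.residue_name,
                a.is_polymer,
            )
            for a in self.atoms
        ]
        return AtomicStructure(atoms, self.source_id, self.model_count_merged)


@dataclass(frozen=True)
class Subunit:
    """One chain or discrete chemical molecule with its assigned class."""

    subunit_id: str
    cls: str  # protein | carbohydrate | cyclodextrin | other
    atom_indices: tuple[int, ...]


@dataclass
class SubunitPartition:
    """Disjoint cover of a structure's atoms by typed subunits."""

    subunits: list[Subunit]

    def by_class(self, cls: str) -> list[Subunit]:
        return [s for s in self.subunits if s.cls == cls]

    def classes(self) -> set[str]:
        return {s.cls for s in self.subunits}

    def atom_indices_of_class(self, cls: str) -> np.ndarray:
        idx: list[int] = []
        for s in self.by_class(cls):
            idx.extend(s.atom_indices)
        return np.array(sorted(idx), dtype=np.intp)


# Common PDB chemical-component codes for monosaccharides and frequent
# derivatives.  This shipped default is deliberately user-overridable: the
# curated vocabulary used for any given dataset is a modelling decision.
_DEFAULT_CARB_CODES = {
    "GLC", "BGC", "GAL", "GLA", "MAN", "BMA", "FUC", "FUL", "XYP", "XYS",
    "FRU", "RIB", "ARA", "ARB", "RAM", "RM4", "SIA", "SLB", "NAG", "NDG",
    "A2G", "NGA", "GCS", "GCU", "BDP", "IDS", "IDR", "GCD", "KDO", "DHA",
    "MUB", "AMU", "G6D", "GLP", "G6P", "F6P", "SUC", "TRE", "MAL", "LAT",
    "LBT", "CEL", "BHG", "MMA", "AHR", "LYX", "TAG", "SOR", "PSI", "ALL",
}
# cyclodextrin assembly component codes (cyclic glucopyranose oligomers):
# ACX alpha-, BCD beta-cyclodextrin; extend via a vocabulary file for others
_DEFAULT_CD_CODES = {"ACX", "BCD"}


@dataclass
class CarbVocabulary:
    """Residue-code vocabulary separating carbohydrates from cyclodextrins.

    Cyclodextrin codes are always also members of the carbohydrate set
    (a cyclodextrin *is* a glucopyranose oligomer) but carry the distinct
    ``cyclodextrin`` class during partitioning.
    """

    carbohydrate_codes: set[str] = field(default_factory=lambda: set(_DEFAULT_CARB_CODES))
    cyclodextrin_codes: set[str] = field(default_factory=lambda: set(_DEFAULT_CD_CODES))

    def __post_init__(self):
        self.carbohydrate_codes = {c.upper() for c in self.carbohydrate_codes}
        self.cyclodextrin_codes = {c.upper() for c in self.cyclodextrin_codes}
        if not self.carbohydrate_codes or not self.cyclodextrin_codes:
            raise ValueError("vocabulary code sets must be non-empty")
        self.carbohydrate_codes |= self.cyclodextrin_codes

    @classmethod
    def from_file(cls, path: str | Path) -> "CarbVocabulary":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(
            carbohydrate_codes=set(raw["carbohydrate_codes"]),
            cyclodextrin_codes=set(raw["cyclodextrin_codes"]),
        )

    def to_file(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {
                    "carbohydrate_codes": sorted(self.carbohydrate_codes),
                    "cyclodextrin_codes": sorted(self.cyclodextrin_codes),
                },
                fh,
            )


DEFAULT_VOCAB = CarbVocabulary()


def _is_amino_acid(residue_name: str) -> bool:
    info = gemmi.find_tabulated_residue(residue_name)
    return info is not None and info.is_amino_acid()


def load_structure(path: str | Path, fmt: str = "auto") -> AtomicStructure:
    """Load a PDB or mmCIF file into a single entity.

    Every model of a multi-model file is concatenated into one entity; chains
    of models beyond the first get a ``#<model>`` suffix so residue keys stay
    unique.  Alternate locations are resolved by keeping the highest-occupancy
    conformer of each atom.  Atom order follows file order.
    """
    path = Path(path)
    if not path.exists():
        raise StructureError(f"no such file: {path}")
    fmt = fmt.lower()
    if fmt == "auto":
        fmt_map = gemmi.CoorFormat.Detect
    elif fmt == "pdb":
        fmt_map = gemmi.CoorFormat.Pdb
    elif fmt in ("mmcif", "cif"):
        fmt_map = gemmi.CoorFormat.Mmcif
    else:
        raise StructureError(f"unknown structure format: {fmt!r}")
    try:
        st = gemmi.read_structure(str(path), format=fmt_map)
    except (RuntimeError, ValueError, OSError) as exc:
        raise StructureError(f"cannot parse {path}: {exc}") from exc
    st.setup_entities()

    atoms: list[Atom] = []
    n_models = len(st)
    for i_model, model in enumerate(st):
        suffix = "" if i_model == 0 else f"#{i_model + 1}"
        for chain in model:
            polymer_names = {r.name for r in chain.get_polymer()}
            for res in chain:
                is_poly = res.name in polymer_names and _is_amino_acid(res.name)
                # highest-occupancy altloc per atom name
                best: dict[str, gemmi.Atom] = {}
                for at in res:
                    prev = best.get(at.name)
                    if prev is None or at.occ > prev.occ:
                        best[at.name] = at
                for at in res.first_conformer():
                    at = best[at.name]
                    atoms.append(
                        Atom(
                            element=at.element.name.upper(),
                            coords=(at.pos.x, at.pos.y, at.pos.z),
                            atom_name=at.name,
                            residue_key=(
                                chain.name + suffix,
                                res.seqid.num,
                                res.seqid.icode.strip(),
                            ),
                            residue_name=res.name.upper(),
                            is_polymer=is_poly,
                        )
                    )
    if not atoms:
        raise StructureError(f"no atoms parsed from {path}")
    return AtomicStructure(atoms, source_id=path.stem, model_count_merged=n_models)


def _split_molecules(structure: AtomicStructure, residue_ids: list[int],
                     residues) -> list[list[int]]:
    """Group non-polymer residues into molecules by covalent-link distance."""
    n = len(residue_ids)
    coords = structure.coords
    res_coords = [coords[residues[r][2]] for r in residue_ids]
    # union-find over residues closer than the covalent cutoff
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            d = np.linalg.norm(res_coords[i][:, None, :] - res_coords[j][None, :, :], axis=-1)
            if d.min() < COVALENT_LINK_CUTOFF:
                parent[find(i)] = find(j)
    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    # deterministic order: by first residue appearance
    return [sorted(g) for g in sorted(groups.values(), key=min)]


def preprocess(structure: AtomicStructure) -> AtomicStructure:
    """Remove waters and hydrogens; give non-polymer molecules unique chains.

    Idempotent.  Non-polymer molecules (connected components of non-polymer
    residues under a 1.8 Å heavy-atom link distance) are renamed to
    ``<original chain>:<running index>`` so each discrete chemical molecule
    forms its own subunit; polymer chains keep their names.
    """
    kept = [
        a
        for a in structure.atoms
        if a.residue_name not in WATER_NAMES and a.element not in HYDROGEN_ELEMENTS
    ]
    if not kept:
        raise StructureError(f"structure {structure.source_id!r} empty after preprocessing")
    clean = AtomicStructure(kept, structure.source_id, structure.model_count_merged)

    residues = clean.residues()
    # group non-polymer residues by original chain (strip an existing :k suffix
    # so a second pass reproduces the same names -> idempotence)
    nonpoly_by_chain: dict[str, list[int]] = {}
    for r, (key, _name, idx) in enumerate(residues):
        if not clean.atoms[idx[0]].is_polymer:
            base = key[0].split(":")[0]
            nonpoly_by_chain.setdefault(base, []).append(r)

    new_chain: dict[tuple[str, int, str], str] = {}
    for base, res_ids in nonpoly_by_chain.items():
        molecules = _split_molecules(clean, res_ids, residues)
        for k, mol in enumerate(molecules, start=1):
            for local in mol:
                r = res_ids[local]
                new_chain[residues[r][0]] = f"{base}:{k}"

    if not new_chain:
        return clean
    atoms = [
        Atom(
            a.element,
            a.coords,
            a.atom_name,
            (new_chain.get(a.residue_key, a.residue_key[0]),) + a.residue_key[1:],
            a.residue_name,
            a.is_polymer,
        )
        for a in clean.atoms
    ]
    return AtomicStructure(atoms, clean.source_id, clean.model_count_merged)


def partition_subunits(
    structure: AtomicStructure, vocab: CarbVocabulary | None = None
) -> SubunitPartition:
    """Assign every atom to a typed subunit.

    Polymer amino-acid chains become ``protein`` subunits (one per chain).
    Within non-polymer chains, maximal runs of residues sharing a class are
    one subunit each: ``cyclodextrin`` codes take priority over plain
    ``carbohydrate`` codes; unknown codes fall through to ``other``.
    """
    vocab = vocab or DEFAULT_VOCAB
    residues = structure.residues()

    def residue_class(r: int) -> str:
        key, name, idx = residues[r]
        if structure.atoms[idx[0]].is_polymer:
            return "protein"
        if name in vocab.cyclodextrin_codes:
            return "cyclodextrin"
        if name in vocab.carbohydrate_codes:
            return "carbohydrate"
        return "other"

    subunits: list[Subunit] = []
    run_atoms: list[int] = []
    run_cls: str | None = None
    run_chain: str | None = None

    def flush():
        nonlocal run_atoms
        if run_atoms:
            subunits.append(
                Subunit(f"{run_chain}/{len(subunits)}", run_cls, tuple(run_atoms))
            )
            run_atoms = []

    for r, (key, _name, idx) in enumerate(residues):
        cls = residue_class(r)
        if cls != run_cls or key[0] != run_chain:
            flush()
            run_cls, run_chain = cls, key[0]
        run_atoms.extend(idx)
    flush()
    return SubunitPartition(subunits)


def _short_chain_names(chains: list[str]) -> dict[str, str]:
    """Map chain names to PDB-writable (<=2 char) names, preserving short ones."""
    mapping: dict[str, str] = {}
    used: set[str] = {c for c in chains if len(c) <= 2}
    pool = iter(
        [c for c in string.ascii_uppercase + string.digits + string.ascii_lowercase]
        + [a + b for a in string.ascii_uppercase for b in string.digits]
    )
    for c in chains:
        if len(c) <= 2:
            mapping[c] = c
            continue
        nxt = next(pool)
        while nxt in used:
            nxt = next(pool)
        used.add(nxt)
        mapping[c] = nxt
    return mapping


def _to_gemmi(structure: AtomicStructure, bfactors: np.ndarray | None = None) -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = structure.source_id or "structure"
    model = gemmi.Model(1)
    chain_names = []
    for key, _, _ in structure.residues():
        if key[0] not in chain_names:
            chain_names.append(key[0])
    rename = _short_chain_names(chain_names)
    chains: dict[str, gemmi.Chain] = {}
    res_map: dict[tuple[str, int, str], gemmi.Residue] = {}
    for i, a in enumerate(structure.atoms):
        cname = rename[a.residue_key[0]]
        if cname not in chains:
            chains[cname] = gemmi.Chain(cname)
        if a.residue_key not in res_map:
            res = gemmi.Residue()
            res.name = a.residue_name
            res.seqid = gemmi.SeqId(a.residue_key[1], a.residue_key[2] or " ")
            res.het_flag = "A" if a.is_polymer else "H"
            chains[cname].add_residue(res)
            res_map[a.residue_key] = chains[cname][-1]
        at = gemmi.Atom()
        at.name = a.atom_name
        at.element = gemmi.Element(a.element.capitalize())
        at.pos = gemmi.Position(*a.coords)
        at.occ = 1.0
        at.b_iso = float(bfactors[i]) if bfactors is not None else 0.0
        res_map[a.residue_key].add_atom(at)
    for chain in chains.values():
        model.add_chain(chain)
    st.add_model(model)
    return st


def write_structure(structure: AtomicStructure, path: str | Path) -> None:
    """Write the structure as PDB (chains longer than 2 chars are remapped)."""
    st = _to_gemmi(structure)
    st.setup_entities()
    st.write_pdb(str(path))


def write_predictions(
    structure: AtomicStructure,
    partition: SubunitPartition,
    probabilities: pd.DataFrame,
    pdb_path: str | Path | None = None,
    csv_path: str | Path | None = None,
    cls: str = "carbohydrate",
) -> None:
    """Write per-residue interface probabilities.

    The PDB output carries 100 x probability of ``cls`` in the B-factor
    column of every protein atom; the CSV has one row per protein residue
    with both class probabilities.  ``probabilities`` is the frame returned
    by the model: columns ``chain, resnum, icode, resname, p_carbohydrate,
    p_cyclodextrin`` in protein-residue order.
    """
    if csv_path is not None:
        probabilities.to_csv(csv_path, index=False)
    if pdb_path is None:
        return
    col = f"p_{cls}"
    if col not in probabilities.columns:
        raise ValueError(f"unknown prediction class {cls!r}")
    lookup = {
        (row.chain, int(row.resnum), row.icode or ""): 100.0 * getattr(row, col)
        for row in probabilities.itertuples()
    }
    bf = np.zeros(len(structure))
    for i, a in enumerate(structure.atoms):
        key = (a.residue_key[0], a.residue_key[1], a.residue_key[2])
        bf[i] = lookup.get(key, 0.0)
    st = _to_gemmi(structure, bfactors=bf)
    st.setup_entities()
    st.write_pdb(str(pdb_path))
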