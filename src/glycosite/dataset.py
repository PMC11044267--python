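"""Dataset curation: interface labels, identity clustering and splits.

A residue is part of the binding interface when its minimum heavy-atom
distance to any subunit of the target class is within a 4 Å cutoff
(inclusive), matching the range of known protein-sugar stacking contacts.
Labels are computed independently for the carbohydrate and the cyclodextrin
class, which are exclusive by partitioning.

To avoid train/test leakage, structures are clustered by greedy leader
clustering over global-alignment sequence identity (identity = matches /
alignment length) at a 30% ceiling, and whole clusters — never individual
structures — are apportioned to splits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np
import pandas as pd
from Bio import Align
from scipy.spatial import cKDTree

from .structio import (
    AtomicStructure,
    CarbVocabulary,
    DEFAULT_VOCAB,
    SubunitPartition,
    load_structure,
    partition_subunits,
    preprocess,
)

__all__ = [
    "CLASSES",
    "InterfaceLabels",
    "DatasetEntry",
    "DatasetSplit",
    "contact_labels",
    "protein_sequence",
    "greedy_identity_cluster",
    "assemble_dataset",
    "curate_directory",
]

CLASSES = ("carbohydrate", "cyclodextrin")
DEFAULT_CUTOFF = 4.0       # Å, heavy-atom minimum distance, inclusive
DEFAULT_MAX_IDENTITY = 0.30


@dataclass
class InterfaceLabels:
    """Per-protein-residue binary interface labels, one vector per class."""

    residue_keys: list[tuple[str, int, str]]
    residue_names: list[str]
    y: dict[str, np.ndarray]  # class -> int8 vector over protein residues

    def __post_init__(self):
        n = len(self.residue_keys)
        for cls, vec in self.y.items():
            if len(vec) != n:
                raise ValueError(f"label vector for {cls!r} has wrong length")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chain": [k[0] for k in self.residue_keys],
                "resnum": [k[1] for k in self.residue_keys],
                "icode": [k[2] for k in self.residue_keys],
                "resname": self.residue_names,
                **{f"y_{cls}": self.y[cls].astype(int) for cls in CLASSES},
            }
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "InterfaceLabels":
        keys = [
            (str(c), int(n), "" if pd.isna(i) else str(i))
            for c, n, i in zip(frame["chain"], frame["resnum"], frame["icode"])
        ]
        return cls(
            residue_keys=keys,
            residue_names=[str(r) for r in frame["resname"]],
            y={c: frame[f"y_{c}"].to_numpy(dtype=np.int8) for c in CLASSES},
        )


def protein_residues(
    structure: AtomicStructure, partition: SubunitPartition
) -> list[tuple[tuple[str, int, str], str, list[int]]]:
    """Protein residues in atom order as (key, name, atom indices)."""
    protein_atoms = set()
    for s in partition.by_class("protein"):
        protein_atoms.update(s.atom_indices)
    return [
        (key, name, idx)
        for key, name, idx in structure.residues()
        if idx[0] in protein_atoms
    ]


def contact_labels(
    structure: AtomicStructure,
    partition: SubunitPartition,
    cutoff: float = DEFAULT_CUTOFF,
) -> InterfaceLabels:
    """Label protein residues in contact (min heavy-atom distance <= cutoff)
    with any carbohydrate / cyclodextrin subunit."""
    residues = protein_residues(structure, partition)
    if not residues:
        raise ValueError("structure has no protein subunit")
    coords = structure.coords
    labels: dict[str, np.ndarray] = {}
    for cls in CLASSES:
        y = np.zeros(len(residues), dtype=np.int8)
        lig_idx = partition.atom_indices_of_class(cls)
        if lig_idx.size:
            tree = cKDTree(coords[lig_idx])
            for r, (_key, _name, idx) in enumerate(residues):
                dmin = tree.query(coords[idx], k=1)[0].min()
                y[r] = 1 if dmin <= cutoff else 0
        labels[cls] = y
    return InterfaceLabels(
        residue_keys=[k for k, _, _ in residues],
        residue_names=[n for _, n, _ in residues],
        y=labels,
    )


def protein_sequence(structure: AtomicStructure, partition: SubunitPartition) -> str:
    """One-letter sequence over all protein residues (chains concatenated)."""
    seq = []
    for _key, name, _idx in protein_residues(structure, partition):
        info = gemmi.find_tabulated_residue(name)
        code = info.one_letter_code.upper() if info else "X"
        seq.append(code if code.isalpha() else "X")
    return "".join(seq)


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = 0.0
    aligner.open_gap_score = -0.5
    aligner.extend_gap_score = -0.1
    return aligner


def alignment_identity(a: str, b: str, aligner: Align.PairwiseAligner | None = None) -> float:
    """Global-alignment identity: matches / alignment length (gaps included)."""
    if not a or not b:
        raise ValueError("empty sequence")
    aligner = aligner or _make_aligner()
    aln = aligner.align(a, b)[0]
    counts = aln.counts()
    length = counts.identities + counts.mismatches + counts.gaps
    return counts.identities / length


def greedy_identity_cluster(
    sequences: list[str], max_identity: float = DEFAULT_MAX_IDENTITY
) -> list[int]:
    """Greedy leader clustering: each sequence joins the first cluster whose
    representative exceeds ``max_identity`` identity, else founds a new one.
    Deterministic given input order.  Returns a cluster id per sequence."""
    if not sequences:
        raise ValueError("no sequences to cluster")
    aligner = _make_aligner()
    reps: list[str] = []
    assignment: list[int] = []
    for seq in sequences:
        if not seq:
            raise ValueError("empty sequence")
        for cid, rep in enumerate(reps):
            if alignment_identity(seq, rep, aligner) > max_identity:
                assignment.append(cid)
                break
        else:
            assignment.append(len(reps))
            reps.append(seq)
    return assignment


@dataclass
class DatasetEntry:
    """One curated structure: id, protein sequence and its interface labels."""

    structure_id: str
    sequence: str
    labels: InterfaceLabels
    labels_path: str | None = None


@dataclass
class DatasetSplit:
    train: list[DatasetEntry] = field(default_factory=list)
    val: list[DatasetEntry] = field(default_factory=list)
    test: list[DatasetEntry] = field(default_factory=list)
    cluster_map: dict[str, int] = field(default_factory=dict)

    def split_of(self, structure_id: str) -> str:
        for name in ("train", "val", "test"):
            if any(e.structure_id == structure_id for e in getattr(self, name)):
                return name
        raise KeyError(structure_id)


def assemble_dataset(
    entries: list[DatasetEntry],
    fractions: tuple[float, float, float] = (0.9, 0.05, 0.05),
    seed: int = 0,
    max_identity: float = DEFAULT_MAX_IDENTITY,
) -> DatasetSplit:
    """Cluster entries by sequence identity and apportion whole clusters to
    train/val/test so no cluster spans two splits."""
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    cluster_ids = greedy_identity_cluster([e.sequence for e in entries], max_identity)
    clusters: dict[int, list[DatasetEntry]] = {}
    for e, cid in zip(entries, cluster_ids):
        clusters.setdefault(cid, []).append(e)
    n_nonempty_splits = sum(f > 0 for f in fractions)
    if len(clusters) < n_nonempty_splits:
        raise ValueError(
            f"only {len(clusters)} cluster(s) for {n_nonempty_splits} non-empty splits"
        )
    order = np.random.default_rng(seed).permutation(sorted(clusters))
    split = DatasetSplit(cluster_map={e.structure_id: int(c) for e, c in zip(entries, cluster_ids)})
    targets = [f * len(entries) for f in fractions]
    buckets = (split.train, split.val, split.test)
    filled = [0.0, 0.0, 0.0]
    for cid in order:
        # assign to the non-zero split with the largest remaining deficit
        deficits = [
            (targets[k] - filled[k]) if fractions[k] > 0 else -np.inf for k in range(3)
        ]
        k = int(np.argmax(deficits))
        buckets[k].extend(clusters[int(cid)])
        filled[k] += len(clusters[int(cid)])
    return split


def write_split(split: DatasetSplit, out_dir: str | Path) -> Path:
    """Serialize a split: per-structure label CSVs plus a TSV index."""
    out_dir = Path(out_dir)
    (out_dir / "labels").mkdir(parents=True, exist_ok=True)
    rows = []
    for name in ("train", "val", "test"):
        for e in getattr(split, name):
            label_file = f"labels/{e.structure_id}.csv"
            e.labels.to_frame().to_csv(out_dir / label_file, index=False)
            rows.append(
                {
                    "structure_id": e.structure_id,
                    "split": name,
                    "cluster": split.cluster_map.get(e.structure_id, -1),
                    "label_file": label_file,
                    "sequence": e.sequence,
                }
            )
    index = out_dir / "index.tsv"
    pd.DataFrame(rows).to_csv(index, sep="\t", index=False)
    return index


def read_split(index_path: str | Path) -> DatasetSplit:
    index_path = Path(index_path)
    frame = pd.read_csv(index_path, sep="\t", keep_default_na=False)
    split = DatasetSplit()
    for row in frame.itertuples():
        labels = InterfaceLabels.from_frame(
            pd.read_csv(index_path.parent / row.label_file, keep_default_na=False)
        )
        entry = DatasetEntry(row.structure_id, row.sequence, labels, row.label_file)
        getattr(split, row.split).append(entry)
        split.cluster_map[row.structure_id] = int(row.cluster)
    return split


def curate_directory(
    input_dir: str | Path,
    out_dir: str | Path,
    vocab: CarbVocabulary | None = None,
    cutoff: float = DEFAULT_CUTOFF,
    max_identity: float = DEFAULT_MAX_IDENTITY,
    fractions: tuple[float, float, float] = (0.9, 0.05, 0.05),
    seed: int = 0,
) -> Path:
    """End-to-end curation of a directory of PDB/mmCIF files into a split."""
    vocab = vocab or DEFAULT_VOCAB
    paths = sorted(
        p
        for p in Path(input_dir).iterdir()
        if p.suffix.lower() in (".pdb", ".ent", ".cif", ".mmcif")
    )
    entries = []
    for p in paths:
        structure = preprocess(load_structure(p))
        partition = partition_subunits(structure, vocab)
        if not partition.by_class("protein"):
            continue
        labels = contact_labels(structure, partition, cutoff)
        entries.append(
            DatasetEntry(structure.source_id, protein_sequence(structure, partition), labels)
        )
    if not entries:
        raise ValueError(f"no usable structures in {input_dir}")
    split = assemble_dataset(entries, fractions, seed, max_identity)
    return write_split(split, out_dir)
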