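"""Readers and writers for the on-disk formats.

Sequences travel as FASTA, everything else as tab-separated text:
SMILES tables, bipartite edge lists (miRNA-drug, miRNA-gene, drug-gene),
similarity/adjacency matrices with id headers, and prediction tables.
All loaders validate eagerly and fail with the offending id / line number
rather than silently dropping records.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO

logger = logging.getLogger(__name__)

#: Nucleotides accepted in miRNA sequences (both U and T allowed; RNA
#: sequences are normalised to the DNA alphabet only at featurisation time).
SEQUENCE_ALPHABET = frozenset("ACGUT")


class FormatError(ValueError):
    """A file violated its format contract (bad id, alphabet, field count...)."""


@dataclass(frozen=True)
class SequenceRecord:
    """One miRNA: an opaque id plus its nucleotide sequence (uppercase)."""

    entity_id: str
    sequence: str

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        if len(seq) < 3:
            raise FormatError(
                f"sequence for {self.entity_id!r} has length {len(seq)} < 3"
            )
        for pos, ch in enumerate(seq, start=1):
            if ch not in SEQUENCE_ALPHABET:
                raise FormatError(
                    f"illegal character {ch!r} at position {pos} "
                    f"in sequence {self.entity_id!r}"
                )


@dataclass(frozen=True)
class DrugRecord:
    """One drug: an opaque id plus its SMILES string (parsed lazily)."""

    entity_id: str
    smiles: str


@dataclass(frozen=True)
class PredictionRecord:
    """A scored miRNA-drug pair; label is optional ground truth."""

    mirna_id: str
    drug_id: str
    score: float
    label: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.score <= 1.0:
            raise ValueError(f"score {self.score} outside [0, 1]")
        if self.label is not None and self.label not in (0, 1):
            raise ValueError(f"label must be 0/1, got {self.label}")


@dataclass
class BipartiteAssociations:
    """A binary bipartite incidence structure.

    Row *i* of :meth:`matrix` is the interaction profile IP(row_i): the
    indicator vector of which columns the row entity is linked to.  The
    same structure holds miRNA-drug labels, miRNA-gene profiles and
    drug-gene profiles.
    """

    row_ids: list[str]
    col_ids: list[str]
    pairs: set[tuple[str, str]] = field(default_factory=set)

    def __post_init__(self) -> None:
        if len(set(self.row_ids)) != len(self.row_ids):
            raise FormatError("duplicate row ids")
        if len(set(self.col_ids)) != len(self.col_ids):
            raise FormatError("duplicate column ids")
        rows, cols = set(self.row_ids), set(self.col_ids)
        for r, c in self.pairs:
            if r not in rows:
                raise FormatError(f"pair references unknown row id {r!r}")
            if c not in cols:
                raise FormatError(f"pair references unknown column id {c!r}")

    @property
    def shape(self) -> tuple[int, int]:
        return len(self.row_ids), len(self.col_ids)

    def matrix(self) -> np.ndarray:
        """Dense binary incidence matrix, rows/cols in id-list order."""
        ridx = {r: i for i, r in enumerate(self.row_ids)}
        cidx = {c: j for j, c in enumerate(self.col_ids)}
        out = np.zeros(self.shape, dtype=np.float64)
        for r, c in self.pairs:
            out[ridx[r], cidx[c]] = 1.0
        return out

    def subset_pairs(self, keep: Iterable[tuple[str, str]]) -> "BipartiteAssociations":
        """Same id universe, restricted pair set (used for per-fold rebuilds)."""
        keep = set(keep)
        extra = keep - self.pairs
        if extra:
            raise ValueError(f"{len(extra)} pairs not present in this association set")
        return BipartiteAssociations(list(self.row_ids), list(self.col_ids), keep)


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Load miRNA sequences from FASTA.

    The header token before the first whitespace is the entity id.  Ids must
    be unique; sequences are uppercased and validated against {A,C,G,U,T}
    with length >= 3.
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        eid = entry.id
        if eid in seen:
            raise FormatError(f"duplicate sequence id {eid!r} in {path}")
        seen.add(eid)
        records.append(SequenceRecord(eid, str(entry.seq)))
    return records


def read_smiles_table(path: str | Path) -> list[DrugRecord]:
    """Load a two-column drug-id / SMILES TSV ('#' lines are comments)."""
    path = Path(path)
    records: list[DrugRecord] = []
    seen: set[str] = set()
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 2:
            raise FormatError(
                f"{path}:{lineno}: expected 2 tab-separated fields, got {len(fields)}"
            )
        eid, smiles = fields[0].strip(), fields[1].strip()
        if eid in seen:
            raise FormatError(f"{path}:{lineno}: duplicate drug id {eid!r}")
        seen.add(eid)
        records.append(DrugRecord(eid, smiles))
    return records


def read_edge_list(
    path: str | Path,
    row_ids: Sequence[str] | None = None,
    col_ids: Sequence[str] | None = None,
) -> BipartiteAssociations:
    """Load a bipartite edge list from a 2-column TSV.

    Each data line is ``row_id<TAB>col_id``; lines starting with '#' are
    comments.  A third column (e.g. an association type such as
    resistance/sensitivity) is accepted but ignored with a warning: the
    prediction task is binary existence.  Duplicate pairs collapse to one
    with a warning.  Id order is first appearance unless explicit id lists
    are given (then every id in the file must be in the lists).
    """
    path = Path(path)
    order_rows: list[str] = list(row_ids) if row_ids is not None else []
    order_cols: list[str] = list(col_ids) if col_ids is not None else []
    fixed_rows = row_ids is not None
    fixed_cols = col_ids is not None
    rows_seen, cols_seen = set(order_rows), set(order_cols)
    pairs: set[tuple[str, str]] = set()
    warned_extra_col = False

    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) == 3:
            if not warned_extra_col:
                warnings.warn(
                    f"{path}: third column present; association types are "
                    "ignored (binary existence task)",
                    stacklevel=2,
                )
                warned_extra_col = True
            fields = fields[:2]
        if len(fields) != 2:
            raise FormatError(
                f"{path}:{lineno}: expected 2 tab-separated fields, got {len(fields)}"
            )
        r, c = fields[0].strip(), fields[1].strip()
        if fixed_rows and r not in rows_seen:
            raise FormatError(f"{path}:{lineno}: row id {r!r} not in supplied id list")
        if fixed_cols and c not in cols_seen:
            raise FormatError(f"{path}:{lineno}: column id {c!r} not in supplied id list")
        if not fixed_rows and r not in rows_seen:
            rows_seen.add(r)
            order_rows.append(r)
        if not fixed_cols and c not in cols_seen:
            cols_seen.add(c)
            order_cols.append(c)
        if (r, c) in pairs:
            warnings.warn(f"{path}:{lineno}: duplicate pair ({r}, {c}) collapsed",
                          stacklevel=2)
            continue
        pairs.add((r, c))

    return BipartiteAssociations(order_rows, order_cols, pairs)


def write_edge_list(assoc: BipartiteAssociations, path: str | Path) -> None:
    """Write the pair set as a 2-column TSV, rows sorted for reproducibility."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("#row_id\tcol_id\n")
        for r, c in sorted(assoc.pairs):
            fh.write(f"{r}\t{c}\n")


def write_predictions(records: Iterable[PredictionRecord], path: str | Path) -> None:
    """Write predictions as TSV, sorted by descending score (ties by ids).

    Scores are rendered with 6 significant digits so that a round-trip read
    preserves the ranking.
    """
    recs = sorted(records, key=lambda r: (-r.score, r.mirna_id, r.drug_id))
    path = Path(path)
    with path.open("w") as fh:
        fh.write("mirna_id\tdrug_id\tscore\tlabel\n")
        for r in recs:
            lab = "" if r.label is None else str(r.label)
            fh.write(f"{r.mirna_id}\t{r.drug_id}\t{r.score:.6g}\t{lab}\n")


def read_predictions(path: str | Path) -> list[PredictionRecord]:
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines or lines[0].split("\t")[:3] != ["mirna_id", "drug_id", "score"]:
        raise FormatError(f"{path}: missing prediction header")
    out = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != 4:
            raise FormatError(f"{path}:{lineno}: expected 4 fields")
        label = None if fields[3] == "" else int(fields[3])
        out.append(PredictionRecord(fields[0], fields[1], float(fields[2]), label))
    return out


def write_matrix(ids: Sequence[str], matrix: np.ndarray, path: str | Path) -> None:
    """Serialise a square entity x entity matrix as TSV with id headers."""
    matrix = np.asarray(matrix)
    n = len(ids)
    if matrix.shape != (n, n):
        raise ValueError(f"matrix shape {matrix.shape} does not match {n} ids")
    with Path(path).open("w") as fh:
        fh.write("id\t" + "\t".join(ids) + "\n")
        for i, eid in enumerate(ids):
            fh.write(eid + "\t" + "\t".join(f"{v:.10g}" for v in matrix[i]) + "\n")


def read_matrix(path: str | Path) -> tuple[list[str], np.ndarray]:
    lines = Path(path).read_text().splitlines()
    header = lines[0].split("\t")
    if header[0] != "id":
        raise FormatError(f"{path}: matrix header must start with 'id'")
    ids = header[1:]
    rows = []
    for line in lines[1 : 1 + len(ids)]:
        fields = line.split("\t")
        rows.append([float(v) for v in fields[1:]])
    mat = np.asarray(rows, dtype=np.float64)
    if mat.shape != (len(ids), len(ids)):
        raise FormatError(f"{path}: matrix is not square over its id header")
    return ids, mat
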