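"""The bundled inputs of one prediction problem and its on-disk layout.

A dataset directory contains::

    mirnas.fasta       miRNA sequences (canonical miRNA order = file order)
    fingerprints.tsv   drug id <TAB> 167-char bit string (canonical drug order)
    mda.tsv            known miRNA-drug associations (the labels)
    mga.tsv            miRNA-gene associations
    dga.tsv            drug-gene associations

Drugs may alternatively be given as ``smiles.tsv`` (id <TAB> SMILES), in
which case MACCS fingerprints are computed at load time.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .io import (
    BipartiteAssociations,
    FormatError,
    SequenceRecord,
    read_edge_list,
    read_fasta,
    read_smiles_table,
)
from .views import MACCS_BITS, FingerprintSet, maccs_fingerprints


@dataclass
class Dataset:
    """Sequences, drug fingerprints and the three association tables."""

    sequences: list[SequenceRecord]
    fingerprints: FingerprintSet
    mda: BipartiteAssociations  # rows: miRNAs, cols: drugs (canonical order)
    mga: BipartiteAssociations | None = None
    dga: BipartiteAssociations | None = None

    def __post_init__(self) -> None:
        seq_ids = [r.entity_id for r in self.sequences]
        if list(self.mda.row_ids) != seq_ids:
            raise ValueError("MDA row order must match the sequence order")
        if list(self.mda.col_ids) != list(self.fingerprints.entity_ids):
            raise ValueError("MDA column order must match the fingerprint order")

    @property
    def mirna_ids(self) -> list[str]:
        return list(self.mda.row_ids)

    @property
    def drug_ids(self) -> list[str]:
        return list(self.mda.col_ids)


def read_fingerprint_table(path: str | Path) -> FingerprintSet:
    """Read drug fingerprints stored as id <TAB> bit-string rows."""
    path = Path(path)
    ids, rows = [], []
    seen: set[str] = set()
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        if not raw.strip() or raw.lstrip().startswith("#"):
            continue
        fields = raw.split("\t")
        if len(fields) != 2:
            raise FormatError(f"{path}:{lineno}: expected 2 fields")
        eid, bits = fields
        if eid in seen:
            raise FormatError(f"{path}:{lineno}: duplicate drug id {eid!r}")
        seen.add(eid)
        if len(bits) != MACCS_BITS or set(bits) - {"0", "1"}:
            raise FormatError(
                f"{path}:{lineno}: fingerprint must be {MACCS_BITS} chars of 0/1"
            )
        ids.append(eid)
        rows.append([int(b) for b in bits])
    return FingerprintSet(tuple(ids), np.asarray(rows, dtype=np.float64))


def write_fingerprint_table(fps: FingerprintSet, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("#drug_id\tbits\n")
        for eid, row in zip(fps.entity_ids, fps.bits):
            fh.write(eid + "\t" + "".join(str(int(b)) for b in row) + "\n")


def load_dataset(directory: str | Path) -> Dataset:
    """Load a dataset directory; entity order is frozen from the feature files."""
    d = Path(directory)
    sequences = read_fasta(d / "mirnas.fasta")
    if (d / "fingerprints.tsv").exists():
        fps = read_fingerprint_table(d / "fingerprints.tsv")
    elif (d / "smiles.tsv").exists():
        fps = maccs_fingerprints(read_smiles_table(d / "smiles.tsv"))
    else:
        raise FileNotFoundError(f"{d}: need fingerprints.tsv or smiles.tsv")
    mirna_ids = [r.entity_id for r in sequences]
    drug_ids = list(fps.entity_ids)
    mda = read_edge_list(d / "mda.tsv", row_ids=mirna_ids, col_ids=drug_ids)
    mga = read_edge_list(d / "mga.tsv") if (d / "mga.tsv").exists() else None
    dga = read_edge_list(d / "dga.tsv") if (d / "dga.tsv").exists() else None
    return Dataset(sequences, fps, mda, mga, dga)
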