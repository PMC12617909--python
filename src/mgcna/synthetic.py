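"""Synthetic miRNA-drug datasets with planted bipartite block structure.

The generator emulates the shape of a curated miRNA-drug benchmark: a
sparse bipartite association matrix plus three feature sources (sequences,
structural fingerprints, gene-interaction profiles) whose similarity
structure is correlated with the association pattern.  Entities on both
sides are assigned to latent blocks; aligned miRNA/drug blocks associate
with elevated probability, and each feature source leaks block identity:

* member sequences are enriched for a block-specific 3-mer motif
  (``motif_strength`` = probability of emitting the motif instead of a
  single random nucleotide while growing the sequence);
* drug fingerprints are a per-block 167-bit template with per-bit flip
  noise;
* gene profiles are per-block gene-set templates with per-bit flip noise.

Setting ``motif_strength = 0``, both flip probabilities to 0.5 and the two
association probabilities equal yields a matched no-signal dataset in
which every view is pure noise — the null configuration used for
calibration checks.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import asdict, dataclass, replace
from pathlib import Path

import numpy as np

from ._random import substream
from .dataset import Dataset, write_fingerprint_table
from .io import BipartiteAssociations, SequenceRecord, write_edge_list
from .views import MACCS_BITS, FingerprintSet

RNA_ALPHABET = "ACGU"


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator settings; the defaults define the standard benchmark."""

    n_mirnas: int = 200
    n_drugs: int = 40
    n_genes: int = 300
    n_blocks: int = 4
    within_block_assoc_prob: float = 0.30
    cross_block_assoc_prob: float = 0.02
    motif_strength: float = 0.5
    fingerprint_template_flip_prob: float = 0.1
    gene_profile_noise: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("within_block_assoc_prob", "cross_block_assoc_prob",
                     "motif_strength", "fingerprint_template_flip_prob",
                     "gene_profile_noise"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.n_blocks > min(self.n_mirnas, self.n_drugs):
            raise ValueError("more blocks than entities on one side")
        if self.expected_positives() < 10 * self.n_blocks:
            raise ValueError(
                f"expected positives {self.expected_positives():.1f} < "
                f"{10 * self.n_blocks}; association probabilities too small"
            )

    def expected_positives(self) -> float:
        b = self.n_blocks
        p_same = 1.0 / b
        p = p_same * self.within_block_assoc_prob + \
            (1 - p_same) * self.cross_block_assoc_prob
        return self.n_mirnas * self.n_drugs * p

    def null_counterpart(self) -> "SyntheticConfig":
        """The matched configuration with every planted signal removed."""
        mean_p = (self.within_block_assoc_prob / self.n_blocks
                  + self.cross_block_assoc_prob * (1 - 1 / self.n_blocks))
        return replace(
            self,
            motif_strength=0.0,
            fingerprint_template_flip_prob=0.5,
            gene_profile_noise=0.5,
            within_block_assoc_prob=mean_p,
            cross_block_assoc_prob=mean_p,
        )


@dataclass
class SyntheticDataset:
    """Generated data plus the ground-truth block assignments."""

    dataset: Dataset
    mirna_blocks: dict[str, int]
    drug_blocks: dict[str, int]
    config: SyntheticConfig


def _draw_sequence(rng: np.random.Generator, length: int, motif: str,
                   strength: float) -> str:
    chars: list[str] = []
    while len(chars) < length:
        if strength > 0 and rng.random() < strength:
            chars.extend(motif)
        else:
            chars.append(RNA_ALPHABET[rng.integers(4)])
    return "".join(chars[:length])


def generate(config: SyntheticConfig) -> SyntheticDataset:
    """Build a dataset deterministically from the config and its seed."""
    seed = config.seed
    rng_block = substream(seed, "synthetic/blocks")
    rng_seq = substream(seed, "synthetic/sequences")
    rng_fp = substream(seed, "synthetic/fingerprints")
    rng_gene = substream(seed, "synthetic/genes")
    rng_mda = substream(seed, "synthetic/mda")

    b = config.n_blocks
    mirna_ids = [f"mir{i+1:04d}" for i in range(config.n_mirnas)]
    drug_ids = [f"drug{j+1:03d}" for j in range(config.n_drugs)]
    gene_ids = [f"gene{g+1:04d}" for g in range(config.n_genes)]
    m_block = rng_block.integers(0, b, size=config.n_mirnas)
    d_block = rng_block.integers(0, b, size=config.n_drugs)

    # block-specific 3-mer motifs, distinct across blocks
    all_motifs = ["".join(w) for w in itertools.product(RNA_ALPHABET, repeat=3)]
    motifs = list(rng_block.choice(len(all_motifs), size=b, replace=False))
    motifs = [all_motifs[i] for i in motifs]

    sequences = [
        SequenceRecord(mid, _draw_sequence(
            rng_seq, int(rng_seq.integers(20, 25)), motifs[m_block[i]],
            config.motif_strength))
        for i, mid in enumerate(mirna_ids)
    ]

    fp_templates = (rng_fp.random((b, MACCS_BITS)) < 0.3).astype(np.int64)
    flips = rng_fp.random((config.n_drugs, MACCS_BITS)) \
        < config.fingerprint_template_flip_prob
    bits = np.abs(fp_templates[d_block] - flips.astype(np.int64))
    fingerprints = FingerprintSet(tuple(drug_ids), bits.astype(np.float64))

    def gene_profiles(n, blocks, rng):
        templates = (rng.random((b, config.n_genes)) < 0.15).astype(np.int64)
        noise = rng.random((n, config.n_genes)) < config.gene_profile_noise
        return np.abs(templates[blocks] - noise.astype(np.int64))

    mprof = gene_profiles(config.n_mirnas, m_block, rng_gene)
    dprof = gene_profiles(config.n_drugs, d_block, rng_gene)
    mga = BipartiteAssociations(
        mirna_ids, gene_ids,
        {(mirna_ids[i], gene_ids[g]) for i, g in zip(*np.nonzero(mprof))})
    dga = BipartiteAssociations(
        drug_ids, gene_ids,
        {(drug_ids[i], gene_ids[g]) for i, g in zip(*np.nonzero(dprof))})

    p = np.where(m_block[:, None] == d_block[None, :],
                 config.within_block_assoc_prob,
                 config.cross_block_assoc_prob)
    hits = rng_mda.random(p.shape) < p
    mda = BipartiteAssociations(
        mirna_ids, drug_ids,
        {(mirna_ids[i], drug_ids[j]) for i, j in zip(*np.nonzero(hits))})

    ds = Dataset(sequences, fingerprints, mda, mga, dga)
    return SyntheticDataset(
        ds,
        {mid: int(blk) for mid, blk in zip(mirna_ids, m_block)},
        {did: int(blk) for did, blk in zip(drug_ids, d_block)},
        config,
    )


def write_dataset(sd: SyntheticDataset, directory: str | Path) -> None:
    """Emit the dataset directory plus truth.json with block assignments."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    with (d / "mirnas.fasta").open("w") as fh:
        for rec in sd.dataset.sequences:
            fh.write(f">{rec.entity_id}\n{rec.sequence}\n")
    write_fingerprint_table(sd.dataset.fingerprints, d / "fingerprints.tsv")
    write_edge_list(sd.dataset.mda, d / "mda.tsv")
    write_edge_list(sd.dataset.mga, d / "mga.tsv")
    write_edge_list(sd.dataset.dga, d / "dga.tsv")
    (d / "truth.json").write_text(json.dumps(
        {"config": asdict(sd.config),
         "mirna_blocks": sd.mirna_blocks,
         "drug_blocks": sd.drug_blocks}, indent=2, sort_keys=True) + "\n")
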