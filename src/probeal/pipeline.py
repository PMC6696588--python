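"""Glue between on-disk datasets and in-memory design matrices.

A *data directory* is the file layout produced by ``probeal simulate`` plus
``probeal prepare``:

- ``bioactivity.tsv``        raw Ki records (compound_id, smiles, target_id, ki_nm)
- ``targets.fasta``          target sequences
- ``compound_features.tsv``  precomputed compound vectors (raw fast path)
- ``nonprobe_annotations.tsv`` / ``probe_annotations.tsv``  discretized labels
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import descriptors
from .dataset_prep import AnnotationTable, read_fasta

__all__ = ["PairMatrices", "load_pair_matrices", "matrices_from_dataset"]


@dataclass
class PairMatrices:
    """Design matrices for one descriptor configuration."""

    X_pool: np.ndarray
    y_pool: np.ndarray
    X_ext: np.ndarray
    y_ext: np.ndarray
    feature_names: tuple[str, ...]
    block_boundary: int
    ligand_scheme: str
    target_scheme: str

    @property
    def scheme_tag(self) -> str:
        return f"{self.ligand_scheme}:{self.target_scheme}"


def matrices_from_dataset(
    dataset, target_scheme: str, ligand_scheme: str = "raw"
) -> PairMatrices:
    """Assemble matrices directly from an in-memory synthetic dataset."""
    from .dataset_prep import split_probes

    split = split_probes(dataset.annotations)
    if ligand_scheme == "raw":
        ligand_blocks = descriptors.raw_ligand_blocks(dataset.compound_features)
    else:
        ligand_blocks = descriptors.compute_ligand_blocks(dataset.smiles, ligand_scheme)
    target_blocks = descriptors.compute_target_blocks(dataset.sequences, target_scheme)
    pool_pairs = descriptors.assemble_pairs(
        split.nonprobe_annotations, ligand_blocks, target_blocks
    )
    ext_pairs = descriptors.assemble_pairs(
        split.probe_annotations, ligand_blocks, target_blocks
    )
    X_pool, y_pool, boundary = descriptors.design_matrix(pool_pairs)
    X_ext, y_ext, _ = descriptors.design_matrix(ext_pairs)
    names = descriptors.feature_names(pool_pairs, ligand_blocks, target_blocks)
    return PairMatrices(
        X_pool=X_pool,
        y_pool=y_pool,
        X_ext=X_ext,
        y_ext=y_ext,
        feature_names=names,
        block_boundary=boundary,
        ligand_scheme=ligand_scheme,
        target_scheme=target_scheme,
    )


def _ligand_blocks(data_dir: Path, compounds: set[str], ligand_scheme: str):
    if ligand_scheme == "raw":
        feat_path = data_dir / "compound_features.tsv"
        if not feat_path.exists():
            raise FileNotFoundError(f"{feat_path} required for the raw ligand scheme")
        df = pd.read_csv(feat_path, sep="\t").set_index("compound_id")
        missing = compounds - set(df.index)
        if missing:
            raise ValueError(f"no features for compounds {sorted(missing)[:5]}...")
        return descriptors.raw_ligand_blocks(
            {cid: df.loc[cid].to_numpy(dtype=float) for cid in compounds}
        )
    bio_path = data_dir / "bioactivity.tsv"
    bio = pd.read_csv(bio_path, sep="\t")
    smiles_map = (
        bio.drop_duplicates("compound_id").set_index("compound_id")["smiles"].to_dict()
    )
    missing = compounds - set(smiles_map)
    if missing:
        raise ValueError(f"no SMILES for compounds {sorted(missing)[:5]}...")
    return descriptors.compute_ligand_blocks(
        {cid: smiles_map[cid] for cid in compounds}, ligand_scheme
    )


def load_pair_matrices(
    data_dir: str | Path, ligand_scheme: str, target_scheme: str
) -> PairMatrices:
    """Assemble pool (non-probe) and external (probe) design matrices."""
    data_dir = Path(data_dir)
    pool_table = AnnotationTable.read_csv(data_dir / "nonprobe_annotations.tsv")
    ext_table = AnnotationTable.read_csv(data_dir / "probe_annotations.tsv")
    sequences = read_fasta(data_dir / "targets.fasta")

    compounds = pool_table.compounds | ext_table.compounds
    ligand_blocks = _ligand_blocks(data_dir, compounds, ligand_scheme)
    target_blocks = descriptors.compute_target_blocks(sequences, target_scheme)

    pool_pairs = descriptors.assemble_pairs(pool_table, ligand_blocks, target_blocks)
    ext_pairs = descriptors.assemble_pairs(ext_table, ligand_blocks, target_blocks)
    X_pool, y_pool, boundary = descriptors.design_matrix(pool_pairs)
    X_ext, y_ext, _ = descriptors.design_matrix(ext_pairs)
    names = descriptors.feature_names(pool_pairs, ligand_blocks, target_blocks)
    return PairMatrices(
        X_pool=X_pool,
        y_pool=y_pool,
        X_ext=X_ext,
        y_ext=y_ext,
        feature_names=names,
        block_boundary=boundary,
        ligand_scheme=ligand_scheme,
        target_scheme=target_scheme,
    )
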