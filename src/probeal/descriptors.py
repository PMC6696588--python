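"""Ligand and target descriptor blocks and their concatenation.

Target blocks: per-target one-hot identity vectors, or overlapped
sliding-window k-mer counts of the primary sequence (k = 1..4) over a
run-wide vocabulary.

Ligand blocks: a CATS-style pharmacophore atom-pair count vector
(5 types, 15 unordered type pairs, topological distances 1–10 bonds,
150 entries), hashed circular (Morgan, radius 2) fingerprints folded to
512/1024/4096 bits, and a documented 96-entry physicochemical vector.

Pair instances concatenate the ligand block first, then the target block;
``block_boundary`` records the index separating the two for downstream
feature interpretation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations_with_replacement
from typing import Iterable, Mapping, Sequence

import numpy as np

from rdkit import Chem
from rdkit.Chem import Descriptors, rdMolDescriptors
from rdkit.Chem.QED import qed as _qed
from rdkit import RDLogger

from .dataset_prep import ACTIVE, AnnotationTable

RDLogger.DisableLog("rdApp.*")

logger = logging.getLogger(__name__)

__all__ = [
    "TargetDescriptorBlock",
    "LigandDescriptorBlock",
    "PairInstance",
    "identity_block",
    "build_kmer_vocabulary",
    "kmer_block",
    "cats_block",
    "fingerprint_block",
    "pchem_block",
    "assemble_pairs",
    "design_matrix",
    "compute_ligand_blocks",
    "compute_target_blocks",
    "PCHEM_FEATURE_NAMES",
    "CATS_FEATURE_NAMES",
    "CATS_TYPES",
    "CATS_MAX_DISTANCE",
]

STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")

LIGAND_SCHEMES = ("pchem", "cats", "fp512", "fp1024", "fp4096", "combined", "raw")
TARGET_SCHEMES = ("identity", "residue", "dipeptide", "tripeptide", "tetrapeptide")
TARGET_SCHEME_K = {"residue": 1, "dipeptide": 2, "tripeptide": 3, "tetrapeptide": 4}


@dataclass(frozen=True)
class TargetDescriptorBlock:
    target_id: str
    values: np.ndarray
    vocabulary: tuple[str, ...]

    def __post_init__(self):
        if len(self.values) != len(self.vocabulary):
            raise ValueError("values and vocabulary lengths differ")


@dataclass(frozen=True)
class LigandDescriptorBlock:
    compound_id: str
    values: np.ndarray
    feature_names: tuple[str, ...]
    scheme_tag: str

    def __post_init__(self):
        if len(self.values) != len(self.feature_names):
            raise ValueError("values and feature_names lengths differ")


@dataclass(frozen=True)
class PairInstance:
    """One ligand–target pair: ligand features, then target features."""

    compound_id: str
    target_id: str
    features: np.ndarray
    label: int
    block_boundary: int

    def __post_init__(self):
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0/1, got {self.label}")
        if not 0 <= self.block_boundary <= len(self.features):
            raise ValueError("block_boundary outside feature vector")


# ---------------------------------------------------------------------------
# Target blocks

def identity_block(
    target_index: int, n_targets: int, target_id: str = ""
) -> TargetDescriptorBlock:
    """One-hot identity vector for a target; stacking all gives the identity matrix."""
    if not 0 <= target_index < n_targets:
        raise IndexError(f"target index {target_index} out of range [0, {n_targets})")
    values = np.zeros(n_targets)
    values[target_index] = 1.0
    vocab = tuple(f"target[{i}]" for i in range(n_targets))
    return TargetDescriptorBlock(target_id=target_id, values=values, vocabulary=vocab)


def _windows(sequence: str, k: int) -> Iterable[str]:
    seq = sequence.upper()
    dropped = 0
    for i in range(len(seq) - k + 1):
        w = seq[i : i + k]
        if set(w) <= STANDARD_AA:
            yield w
        else:
            dropped += 1
    if dropped:
        logger.warning("%d window(s) with non-standard residues dropped", dropped)


def build_kmer_vocabulary(sequences: Iterable[str], k: int) -> tuple[str, ...]:
    """Union of observed k-mers across sequences, alphabetically ordered."""
    vocab: set[str] = set()
    for seq in sequences:
        vocab.update(_windows(seq, k))
    return tuple(sorted(vocab))


def kmer_block(
    sequence: str,
    k: int,
    vocabulary: Sequence[str] | None = None,
    target_id: str = "",
) -> TargetDescriptorBlock:
    """Overlapped sliding-window k-mer counts of an amino-acid sequence.

    Counts sum to L - k + 1 for a standard-alphabet sequence of length L.
    With no explicit vocabulary, the sequence's own observed k-mers are
    used; pass the run-wide vocabulary for a fixed-length design matrix.
    """
    if not 1 <= k <= 4:
        raise ValueError(f"k must be in 1..4, got {k}")
    if len(sequence) < k:
        raise ValueError(f"sequence length {len(sequence)} < k={k}")
    counts: dict[str, int] = {}
    for w in _windows(sequence, k):
        counts[w] = counts.get(w, 0) + 1
    vocab = tuple(vocabulary) if vocabulary is not None else tuple(sorted(counts))
    values = np.array([counts.get(w, 0) for w in vocab], dtype=float)
    return TargetDescriptorBlock(target_id=target_id, values=values, vocabulary=vocab)


# ---------------------------------------------------------------------------
# Ligand blocks

def _mol_from_smiles(smiles: str, compound_id: str = "") -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        who = f" for compound {compound_id!r}" if compound_id else ""
        raise ValueError(f"unparseable SMILES {smiles!r}{who}")
    return mol


CATS_TYPES = ("D", "A", "P", "N", "L")  # donor, acceptor, positive, negative, lipophilic
CATS_MAX_DISTANCE = 10
CATS_TYPE_PAIRS = tuple(
    f"{a}-{b}" for a, b in combinations_with_replacement(CATS_TYPES, 2)
)  # 15 unordered pairs
CATS_FEATURE_NAMES = tuple(
    f"cats:{pair}:{d}" for pair in CATS_TYPE_PAIRS for d in range(1, CATS_MAX_DISTANCE + 1)
)  # 150 entries


def _cats_atom_types(mol: Chem.Mol) -> list[set[str]]:
    """Assign pharmacophore types per heavy atom (an atom may carry several).

    Rules (documented approximation of the commercial CATS typing):
    donor      N/O bearing at least one hydrogen;
    acceptor   N/O except pyrrole-type aromatic N (three connections or an H
               inside an aromatic ring);
    positive   formal charge > 0, or a non-aromatic amine N not adjacent to
               a carbonyl carbon (protonatable at pH 7);
    negative   formal charge < 0, or a carboxylic-acid hydroxyl O;
    lipophilic C/Cl/Br/I whose neighbours are all carbon, hydrogen or halogen.
    """
    halogens = {9, 17, 35, 53}
    types: list[set[str]] = []
    for atom in mol.GetAtoms():
        t: set[str] = set()
        z = atom.GetAtomicNum()
        n_h = atom.GetTotalNumHs()
        charge = atom.GetFormalCharge()
        if z in (7, 8):
            if n_h > 0:
                t.add("D")
            pyrrole_like = (
                z == 7
                and atom.GetIsAromatic()
                and (atom.GetDegree() == 3 or n_h > 0)
            )
            if not pyrrole_like and charge <= 0:
                t.add("A")
        if charge > 0:
            t.add("P")
        elif z == 7 and not atom.GetIsAromatic() and n_h > 0:
            adjacent_carbonyl = any(
                nb.GetAtomicNum() == 6
                and any(
                    b.GetBondType() == Chem.BondType.DOUBLE
                    and b.GetOtherAtom(nb).GetAtomicNum() == 8
                    for b in nb.GetBonds()
                )
                for nb in atom.GetNeighbors()
            )
            if not adjacent_carbonyl:
                t.add("P")
        if charge < 0:
            t.add("N")
        elif z == 8 and n_h > 0:
            for nb in atom.GetNeighbors():
                if nb.GetAtomicNum() == 6 and any(
                    b.GetBondType() == Chem.BondType.DOUBLE
                    and b.GetOtherAtom(nb).GetAtomicNum() == 8
                    for b in nb.GetBonds()
                ):
                    t.add("N")
        if z == 6 or z in halogens:
            if all(
                nb.GetAtomicNum() == 6 or nb.GetAtomicNum() in halogens
                for nb in atom.GetNeighbors()
            ):
                t.add("L")
        types.append(t)
    return types


def cats_block(smiles: str, compound_id: str = "") -> LigandDescriptorBlock:
    """CATS-style pharmacophore atom-pair counts: 15 type pairs x distances 1-10.

    Raw (un-normalized) non-negative integer counts; invariant to SMILES
    atom ordering because it is computed on the molecular graph.
    """
    mol = _mol_from_smiles(smiles, compound_id)
    atom_types = _cats_atom_types(mol)
    dmat = Chem.GetDistanceMatrix(mol)
    pair_index = {pair: i for i, pair in enumerate(CATS_TYPE_PAIRS)}
    values = np.zeros(len(CATS_FEATURE_NAMES))
    n_atoms = mol.GetNumAtoms()
    for i in range(n_atoms):
        if not atom_types[i]:
            continue
        for j in range(i + 1, n_atoms):
            if not atom_types[j]:
                continue
            d = int(dmat[i, j])
            if not 1 <= d <= CATS_MAX_DISTANCE:
                continue
            for ti in atom_types[i]:
                for tj in atom_types[j]:
                    a, b = sorted((ti, tj), key=CATS_TYPES.index)
                    values[pair_index[f"{a}-{b}"] * CATS_MAX_DISTANCE + (d - 1)] += 1
    return LigandDescriptorBlock(
        compound_id=compound_id,
        values=values,
        feature_names=CATS_FEATURE_NAMES,
        scheme_tag="cats",
    )


def fingerprint_block(
    smiles: str,
    n_bits: int,
    radius: int = 2,
    compound_id: str = "",
) -> LigandDescriptorBlock:
    """Binary circular (Morgan) fingerprint folded to ``n_bits``."""
    if n_bits not in (512, 1024, 4096):
        raise ValueError(f"n_bits must be one of 512/1024/4096, got {n_bits}")
    mol = _mol_from_smiles(smiles, compound_id)
    from rdkit.Chem import rdFingerprintGenerator

    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    fp = gen.GetFingerprint(mol)
    values = np.zeros(n_bits)
    for bit in fp.GetOnBits():
        values[bit] = 1.0
    names = tuple(f"fp{n_bits}:bit{i:04d}" for i in range(n_bits))
    return LigandDescriptorBlock(
        compound_id=compound_id,
        values=values,
        feature_names=names,
        scheme_tag=f"fp{n_bits}",
    )


# --- physicochemical block -------------------------------------------------

def _element_count(z: int):
    return lambda m: sum(1 for a in m.GetAtoms() if a.GetAtomicNum() == z)


def _n_hydrogens(m):
    return sum(a.GetTotalNumHs() for a in m.GetAtoms())


def _n_atoms_total(m):
    return m.GetNumAtoms() + _n_hydrogens(m)


def _n_halogens(m):
    return sum(1 for a in m.GetAtoms() if a.GetAtomicNum() in (9, 17, 35, 53))


def _pct_element(z: int):
    def f(m):
        total = _n_atoms_total(m)
        n = _n_hydrogens(m) if z == 1 else _element_count(z)(m)
        return 100.0 * n / total if total else 0.0

    return f


def _pct_halogen(m):
    total = _n_atoms_total(m)
    return 100.0 * _n_halogens(m) / total if total else 0.0


def _bond_count(order):
    return lambda m: sum(1 for b in m.GetBonds() if b.GetBondType() == order)


def _n_aromatic_bonds(m):
    return sum(1 for b in m.GetBonds() if b.GetIsAromatic())


def _carbon_hyb(hyb):
    return lambda m: sum(
        1
        for a in m.GetAtoms()
        if a.GetAtomicNum() == 6 and a.GetHybridization() == hyb
    )


def _n_aromatic_atoms(m):
    return sum(1 for a in m.GetAtoms() if a.GetIsAromatic())


def _n_aromatic_of(z: int):
    return lambda m: sum(
        1 for a in m.GetAtoms() if a.GetIsAromatic() and a.GetAtomicNum() == z
    )


def _mean_atomic_number(m):
    zs = [a.GetAtomicNum() for a in m.GetAtoms()]
    return float(np.mean(zs)) if zs else 0.0


def _cyclomatic(m):
    return m.GetNumBonds() - m.GetNumAtoms() + len(Chem.GetMolFrags(m))


def _ring_sizes(m):
    return [len(r) for r in m.GetRingInfo().AtomRings()]


def _n_rings_of_size(size: int):
    return lambda m: sum(1 for s in _ring_sizes(m) if s == size)


def _n_aromatic_rings_of_size(size: int):
    def f(m):
        ri = m.GetRingInfo()
        n = 0
        for ring in ri.AtomRings():
            if len(ring) == size and all(
                m.GetAtomWithIdx(i).GetIsAromatic() for i in ring
            ):
                n += 1
        return n

    return f


def _n_ring_atoms(m):
    return sum(1 for a in m.GetAtoms() if a.IsInRing())


def _n_ring_bonds(m):
    return sum(1 for b in m.GetBonds() if b.IsInRing())


def _fraction_ring_atoms(m):
    n = m.GetNumAtoms()
    return _n_ring_atoms(m) / n if n else 0.0


def _largest_ring(m):
    sizes = _ring_sizes(m)
    return max(sizes) if sizes else 0


def _smallest_ring(m):
    sizes = _ring_sizes(m)
    return min(sizes) if sizes else 0


def _n_fused_ring_bonds(m):
    ri = m.GetRingInfo()
    return sum(1 for b in m.GetBonds() if ri.NumBondRings(b.GetIdx()) >= 2)


def _n_ring_heteroatoms(m):
    return sum(
        1 for a in m.GetAtoms() if a.IsInRing() and a.GetAtomicNum() not in (1, 6)
    )


def _safe(fn):
    def f(m):
        try:
            v = fn(m)
        except Exception:  # pragma: no cover - defensive
            return 0.0
        return 0.0 if v is None or not np.isfinite(v) else float(v)

    return f


_CONSTITUTIONAL = [
    ("mol_weight", Descriptors.MolWt),
    ("heavy_atom_mol_weight", Descriptors.HeavyAtomMolWt),
    ("exact_mol_weight", Descriptors.ExactMolWt),
    ("mean_atom_weight", lambda m: Descriptors.MolWt(m) / max(_n_atoms_total(m), 1)),
    ("n_atoms", _n_atoms_total),
    ("n_heavy_atoms", lambda m: m.GetNumAtoms()),
    ("n_hydrogens", _n_hydrogens),
    ("n_carbons", _element_count(6)),
    ("n_nitrogens", _element_count(7)),
    ("n_oxygens", _element_count(8)),
    ("n_sulfurs", _element_count(16)),
    ("n_phosphorus", _element_count(15)),
    ("n_fluorines", _element_count(9)),
    ("n_chlorines", _element_count(17)),
    ("n_bromines", _element_count(35)),
    ("n_iodines", _element_count(53)),
    ("n_halogens", _n_halogens),
    ("n_heteroatoms", Descriptors.NumHeteroatoms),
    ("pct_hydrogen", _pct_element(1)),
    ("pct_carbon", _pct_element(6)),
    ("pct_nitrogen", _pct_element(7)),
    ("pct_oxygen", _pct_element(8)),
    ("pct_halogen", _pct_halogen),
    ("n_bonds", lambda m: m.GetNumBonds()),
    ("n_single_bonds", _bond_count(Chem.BondType.SINGLE)),
    ("n_double_bonds", _bond_count(Chem.BondType.DOUBLE)),
    ("n_triple_bonds", _bond_count(Chem.BondType.TRIPLE)),
    ("n_aromatic_bonds", _n_aromatic_bonds),
    ("n_rotatable_bonds", Descriptors.NumRotatableBonds),
    ("n_valence_electrons", Descriptors.NumValenceElectrons),
    ("n_radical_electrons", Descriptors.NumRadicalElectrons),
    ("formal_charge", Chem.GetFormalCharge),
    ("n_hbond_donors", Descriptors.NumHDonors),
    ("n_hbond_acceptors", Descriptors.NumHAcceptors),
    ("nhoh_count", Descriptors.NHOHCount),
    ("no_count", Descriptors.NOCount),
    ("fraction_csp3", Descriptors.FractionCSP3),
    ("n_sp_carbons", _carbon_hyb(Chem.HybridizationType.SP)),
    ("n_sp2_carbons", _carbon_hyb(Chem.HybridizationType.SP2)),
    ("n_sp3_carbons", _carbon_hyb(Chem.HybridizationType.SP3)),
    ("n_amide_bonds", rdMolDescriptors.CalcNumAmideBonds),
    ("n_aromatic_atoms", _n_aromatic_atoms),
    ("n_aromatic_carbons", _n_aromatic_of(6)),
    ("n_aromatic_nitrogens", _n_aromatic_of(7)),
    ("mean_atomic_number", _mean_atomic_number),
    ("cyclomatic_number", _cyclomatic),
    ("n_fragments", lambda m: len(Chem.GetMolFrags(m))),
]

_RING = [
    ("ring_count", Descriptors.RingCount),
    ("n_aromatic_rings", Descriptors.NumAromaticRings),
    ("n_aliphatic_rings", Descriptors.NumAliphaticRings),
    ("n_saturated_rings", Descriptors.NumSaturatedRings),
    ("n_aromatic_carbocycles", Descriptors.NumAromaticCarbocycles),
    ("n_aromatic_heterocycles", Descriptors.NumAromaticHeterocycles),
    ("n_aliphatic_carbocycles", Descriptors.NumAliphaticCarbocycles),
    ("n_aliphatic_heterocycles", Descriptors.NumAliphaticHeterocycles),
    ("n_saturated_carbocycles", Descriptors.NumSaturatedCarbocycles),
    ("n_saturated_heterocycles", Descriptors.NumSaturatedHeterocycles),
    *[(f"n_rings_size{s}", _n_rings_of_size(s)) for s in range(3, 13)],
    ("n_aromatic_rings_size5", _n_aromatic_rings_of_size(5)),
    ("n_aromatic_rings_size6", _n_aromatic_rings_of_size(6)),
    ("n_aromatic_rings_size7", _n_aromatic_rings_of_size(7)),
    ("n_ring_atoms", _n_ring_atoms),
    ("n_ring_bonds", _n_ring_bonds),
    ("fraction_ring_atoms", _fraction_ring_atoms),
    ("largest_ring_size", _largest_ring),
    ("smallest_ring_size", _smallest_ring),
    ("n_fused_ring_bonds", _n_fused_ring_bonds),
    ("n_bridgehead_atoms", rdMolDescriptors.CalcNumBridgeheadAtoms),
    ("n_spiro_atoms", rdMolDescriptors.CalcNumSpiroAtoms),
    ("n_ring_heteroatoms", _n_ring_heteroatoms),
]

_PROPERTIES = [
    ("logp", Descriptors.MolLogP),
    ("molar_refractivity", Descriptors.MolMR),
    ("tpsa", Descriptors.TPSA),
    ("labute_asa", Descriptors.LabuteASA),
    ("balaban_j", Descriptors.BalabanJ),
    ("bertz_ct", Descriptors.BertzCT),
    ("hall_kier_alpha", Descriptors.HallKierAlpha),
    ("kappa1", Descriptors.Kappa1),
    ("kappa2", Descriptors.Kappa2),
    ("kappa3", Descriptors.Kappa3),
    ("chi0v", Descriptors.Chi0v),
    ("chi1v", Descriptors.Chi1v),
    ("chi2v", Descriptors.Chi2v),
    ("chi3v", Descriptors.Chi3v),
    ("chi4v", Descriptors.Chi4v),
    ("max_partial_charge", Descriptors.MaxPartialCharge),
    ("min_partial_charge", Descriptors.MinPartialCharge),
    ("max_abs_partial_charge", Descriptors.MaxAbsPartialCharge),
    ("min_abs_partial_charge", Descriptors.MinAbsPartialCharge),
    ("qed", _qed),
]

# Block sizes mirror the reference physicochemical set: 47 constitutional +
# 32 ring + 20 property descriptors, minus 3 entries standing in for the
# removed toxicity estimates.
PCHEM_BLOCK_SIZES = (len(_CONSTITUTIONAL), len(_RING), len(_PROPERTIES))
PCHEM_EXCLUDED = ("max_abs_partial_charge", "min_abs_partial_charge", "qed")

_PCHEM = [
    (name, fn)
    for name, fn in (_CONSTITUTIONAL + _RING + _PROPERTIES)
    if name not in PCHEM_EXCLUDED
]
PCHEM_FEATURE_NAMES = tuple(f"pchem:{name}" for name, _ in _PCHEM)

assert PCHEM_BLOCK_SIZES == (47, 32, 20)
assert len(PCHEM_FEATURE_NAMES) == sum(PCHEM_BLOCK_SIZES) - len(PCHEM_EXCLUDED) == 96


def pchem_block(smiles: str, compound_id: str = "") -> LigandDescriptorBlock:
    """96 fixed-order physicochemical descriptors (open-source substitutes)."""
    mol = _mol_from_smiles(smiles, compound_id)
    values = np.array([_safe(fn)(mol) for _, fn in _PCHEM])
    return LigandDescriptorBlock(
        compound_id=compound_id,
        values=values,
        feature_names=PCHEM_FEATURE_NAMES,
        scheme_tag="pchem",
    )


# ---------------------------------------------------------------------------
# Assembly

def compute_ligand_blocks(
    smiles_by_compound: Mapping[str, str], scheme: str
) -> dict[str, LigandDescriptorBlock]:
    """Compute the requested ligand block for every compound.

    ``combined`` concatenates the physicochemical block with the 1024-bit
    fingerprint block.
    """
    if scheme not in LIGAND_SCHEMES:
        raise ValueError(f"unknown ligand scheme {scheme!r}")
    blocks: dict[str, LigandDescriptorBlock] = {}
    failures: list[str] = []
    for cid, smiles in smiles_by_compound.items():
        try:
            if scheme == "pchem":
                blocks[cid] = pchem_block(smiles, cid)
            elif scheme == "cats":
                blocks[cid] = cats_block(smiles, cid)
            elif scheme.startswith("fp"):
                blocks[cid] = fingerprint_block(smiles, int(scheme[2:]), compound_id=cid)
            elif scheme == "combined":
                p = pchem_block(smiles, cid)
                f = fingerprint_block(smiles, 1024, compound_id=cid)
                blocks[cid] = LigandDescriptorBlock(
                    compound_id=cid,
                    values=np.concatenate([p.values, f.values]),
                    feature_names=p.feature_names + f.feature_names,
                    scheme_tag="combined",
                )
            else:  # raw: smiles_by_compound maps to precomputed vectors elsewhere
                raise ValueError("raw scheme takes precomputed vectors, not SMILES")
        except ValueError as exc:
            failures.append(f"{cid}: {exc}")
    if failures:
        raise ValueError("ligand descriptor failures:\n" + "\n".join(failures))
    return blocks


def raw_ligand_blocks(
    features_by_compound: Mapping[str, np.ndarray]
) -> dict[str, LigandDescriptorBlock]:
    """Wrap precomputed per-compound feature vectors (synthetic fast path)."""
    blocks = {}
    for cid, vec in features_by_compound.items():
        vec = np.asarray(vec, dtype=float)
        names = tuple(f"raw:x{i:03d}" for i in range(len(vec)))
        blocks[cid] = LigandDescriptorBlock(
            compound_id=cid, values=vec, feature_names=names, scheme_tag="raw"
        )
    return blocks


def compute_target_blocks(
    sequences: Mapping[str, str], scheme: str
) -> dict[str, TargetDescriptorBlock]:
    """Compute identity or k-mer blocks for every target (fixed run-wide vocabulary)."""
    if scheme not in TARGET_SCHEMES:
        raise ValueError(f"unknown target scheme {scheme!r}")
    target_ids = sorted(sequences)
    if scheme == "identity":
        return {
            tid: identity_block(i, len(target_ids), target_id=tid)
            for i, tid in enumerate(target_ids)
        }
    k = TARGET_SCHEME_K[scheme]
    vocab = build_kmer_vocabulary((sequences[t] for t in target_ids), k)
    return {
        tid: kmer_block(sequences[tid], k, vocabulary=vocab, target_id=tid)
        for tid in target_ids
    }


def assemble_pairs(
    annotations: AnnotationTable,
    ligand_blocks: Mapping[str, LigandDescriptorBlock],
    target_blocks: Mapping[str, TargetDescriptorBlock],
) -> list[PairInstance]:
    """Concatenate ligand-then-target blocks into one instance per annotation row."""
    missing_c = sorted(annotations.compounds - set(ligand_blocks))
    missing_t = sorted(annotations.targets - set(target_blocks))
    if missing_c or missing_t:
        raise ValueError(
            f"missing descriptors — compounds: {missing_c}, targets: {missing_t}"
        )
    pairs: list[PairInstance] = []
    for row in annotations.rows.itertuples(index=False):
        lig = ligand_blocks[row.compound_id]
        tgt = target_blocks[row.target_id]
        pairs.append(
            PairInstance(
                compound_id=row.compound_id,
                target_id=row.target_id,
                features=np.concatenate([lig.values, tgt.values]),
                label=1 if row.label == ACTIVE else 0,
                block_boundary=len(lig.values),
            )
        )
    return pairs


def design_matrix(
    pairs: Sequence[PairInstance],
) -> tuple[np.ndarray, np.ndarray, int]:
    """Stack pair instances into (X, y, block_boundary)."""
    if not pairs:
        raise ValueError("no pair instances")
    boundaries = {p.block_boundary for p in pairs}
    if len(boundaries) != 1:
        raise ValueError("inconsistent block boundaries")
    X = np.vstack([p.features for p in pairs])
    y = np.array([p.label for p in pairs], dtype=int)
    return X, y, boundaries.pop()


def write_descriptor_matrix(blocks: Mapping[str, object], path) -> None:
    """Write ligand or target blocks as delimited text, one named column per feature.

    Accepts a mapping of id -> LigandDescriptorBlock / TargetDescriptorBlock
    (all sharing one feature space).
    """
    import pandas as pd

    ids = sorted(blocks)
    if not ids:
        raise ValueError("no descriptor blocks to write")
    first = blocks[ids[0]]
    names = getattr(first, "feature_names", None) or tuple(
        f"target:{v}" for v in first.vocabulary
    )
    rows = np.vstack([blocks[i].values for i in ids])
    df = pd.DataFrame(rows, columns=list(names))
    df.insert(0, "id", ids)
    df.to_csv(path, sep="\t", index=False)


def feature_names(
    pairs: Sequence[PairInstance],
    ligand_blocks: Mapping[str, LigandDescriptorBlock],
    target_blocks: Mapping[str, TargetDescriptorBlock],
) -> tuple[str, ...]:
    """Feature names for an assembled design matrix (ligand block then target)."""
    p = pairs[0]
    lig = ligand_blocks[p.compound_id]
    tgt = target_blocks[p.target_id]
    return lig.feature_names + tuple(f"target:{v}" for v in tgt.vocabulary)
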