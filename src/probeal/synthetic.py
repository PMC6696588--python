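"""Synthetic ligand–target bioactivity data with known ground truth.

The generator emulates the statistical shape the analysis assumes: a small
target family (default 9 targets), ~1200 compounds, ~2400 binary
annotations, per-target active fractions spanning a wide range, a minority
of compounds satisfying the probe definition, and target-specific local
structure–activity rules tied to target sequences.

Structure of the ground truth:

- Targets fall into a few groups.  Each group has a signature amino acid
  that is enriched in its members' sequences, so k-mer descriptors cluster
  targets by group; each target additionally carries one planted k-mer
  motif unique to it family-wide.
- Each target's activity rule thresholds one group-specific chemical
  feature: a compound is active on target t when x[g(t)] exceeds a
  per-target threshold calibrated to the target's drawn active fraction.
  Labels are flipped independently at a configurable noise rate.
- Ki values are back-generated on the correct side of the per-target
  discretization thresholds, so the raw-record path through
  :mod:`probeal.dataset_prep` reproduces the generated labels exactly.

Two compound representations ship: raw feature vectors (fast path) and
template-derived SMILES whose rule features are standardized RDKit
descriptors (full-pipeline path).
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .dataset_prep import (
    ACTIVE,
    INACTIVE,
    AnnotationTable,
    BioactivityRecord,
    write_fasta,
)

__all__ = [
    "SynthConfig",
    "GroundTruth",
    "SynthDataset",
    "generate",
    "make_probe_compounds",
    "reference_config",
]

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
SIGNATURE_LETTERS = "WHMQYFKE"  # one per group, in order

# rule-feature descriptors for the SMILES path (standardized across the library)
_SMILES_RULE_DESCRIPTORS = (
    "mol_weight",
    "logp",
    "tpsa",
    "ring_count",
    "n_hbond_acceptors",
    "n_hbond_donors",
    "n_rotatable_bonds",
    "n_halogens",
)

_FRAGMENTS = ("C", "CC", "CCC", "O", "N", "CO", "CN", "c1ccccc1", "C1CCCC1", "C(=O)O", "S")
_TERMINALS = ("", "Cl", "Br", "F", "O", "N", "C#N", "C(=O)O")


@dataclass
class SynthConfig:
    """Knobs for the generator; defaults mirror the reference dataset shape."""

    n_targets: int = 9
    n_compounds: int = 1200
    annotation_density: float = 0.22
    active_fraction_range: tuple[float, float] = (0.19, 0.88)
    probe_fraction: float = 0.06
    sequence_length_range: tuple[int, int] = (90, 130)
    motif_length: int = 3
    n_chemical_features: int = 12
    n_groups: int = 3
    potency_weight: float = 2.0
    noise_rate: float = 0.05
    group_fraction_jitter: float = 0.04
    home_group_bias: float = 8.0
    group_motif_copies: int = 6
    signature_enrichment: float = 0.12
    smiles: bool = False
    rng_seed: int = 0

    def __post_init__(self):
        if self.n_targets < 2:
            raise ValueError("need at least 2 targets (probe definition)")
        if not 0 < self.annotation_density <= 1:
            raise ValueError("annotation density must lie in (0, 1]")
        lo, hi = self.active_fraction_range
        if not (0 < lo <= hi < 1):
            raise ValueError("active fraction range must lie inside (0, 1)")
        if not 0 <= self.probe_fraction < 1:
            raise ValueError("probe fraction must lie in [0, 1)")
        if self.n_groups > self.n_targets:
            raise ValueError("more groups than targets")
        if self.n_groups + 1 > self.n_chemical_features and not self.smiles:
            raise ValueError("need one potency feature plus one feature per group")
        if self.n_groups > len(SIGNATURE_LETTERS):
            raise ValueError(f"at most {len(SIGNATURE_LETTERS)} groups supported")


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must rediscover."""

    group_of: dict[str, int]
    signature_letters: dict[int, str]
    planted_motifs: dict[str, str]
    group_motifs: dict[int, str]
    rule_feature: dict[str, int]
    rule_threshold: dict[str, float]
    potency_weight: float
    target_active_fraction: dict[str, float]
    planted_probes: set[str] = field(default_factory=set)
    probe_compounds: set[str] = field(default_factory=set)
    noise_flips: set[tuple[str, str]] = field(default_factory=set)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "group_of": self.group_of,
            "signature_letters": {str(k): v for k, v in self.signature_letters.items()},
            "planted_motifs": self.planted_motifs,
            "group_motifs": {str(k): v for k, v in self.group_motifs.items()},
            "rule_feature": self.rule_feature,
            "rule_threshold": self.rule_threshold,
            "potency_weight": self.potency_weight,
            "target_active_fraction": self.target_active_fraction,
            "planted_probes": sorted(self.planted_probes),
            "probe_compounds": sorted(self.probe_compounds),
            "noise_flips": sorted(map(list, self.noise_flips)),
        }
        Path(path).write_text(json.dumps(payload, indent=2))


@dataclass
class SynthDataset:
    """Generator output bundle: raw records, labels, sequences, features, truth."""

    config: SynthConfig
    records: list[BioactivityRecord]
    annotations: AnnotationTable
    sequences: dict[str, str]
    compound_features: dict[str, np.ndarray]
    smiles: dict[str, str]
    truth: GroundTruth
    # SMILES path only: (mean, sd) standardizing raw descriptor features
    feature_scaler: tuple[np.ndarray, np.ndarray] | None = None

    def feature_matrix(self) -> tuple[list[str], np.ndarray]:
        ids = sorted(self.compound_features)
        return ids, np.vstack([self.compound_features[c] for c in ids])

    def to_files(self, outdir: str | Path) -> dict[str, str]:
        """Write the dataset as plain text: bioactivity TSV, FASTA, features, truth."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        rows = [
            {
                "compound_id": r.compound_id,
                "smiles": r.smiles,
                "target_id": r.target_id,
                "ki_nm": r.ki_nm,
            }
            for r in self.records
        ]
        paths["bioactivity"] = str(outdir / "bioactivity.tsv")
        pd.DataFrame(rows).to_csv(paths["bioactivity"], sep="\t", index=False)
        paths["targets"] = str(outdir / "targets.fasta")
        write_fasta(self.sequences, paths["targets"])
        ids, X = self.feature_matrix()
        feat = pd.DataFrame(X, columns=[f"x{i:03d}" for i in range(X.shape[1])])
        feat.insert(0, "compound_id", ids)
        paths["features"] = str(outdir / "compound_features.tsv")
        feat.to_csv(paths["features"], sep="\t", index=False)
        paths["annotations"] = str(outdir / "annotations.tsv")
        self.annotations.to_csv(paths["annotations"])
        paths["truth"] = str(outdir / "ground_truth.json")
        self.truth.to_json(paths["truth"])
        return paths


def reference_config(name: str = "balanced", rng_seed: int = 0, **overrides) -> SynthConfig:
    """Scaled-down named configurations used by the test and benchmark suites.

    - ``balanced``   default active-fraction span (wide, mean near 0.5);
      used for descriptor-comparison and interpretation benchmarks.
    - ``imbalanced`` moderate minority-active pools with enough actives to
      sustain 100 balanced picks; used for pick-balance benchmarks.
    - ``sparse``     rare-active pools where random picking demonstrably
      starves of actives; used for picker-comparison benchmarks.

    All are ~150–180 compounds so a full fit–predict–pick trajectory to a
    25% budget runs in seconds on one CPU.
    """
    presets = {
        "balanced": dict(n_compounds=150, probe_fraction=0.18),
        "imbalanced": dict(
            n_compounds=180, probe_fraction=0.18, active_fraction_range=(0.10, 0.35)
        ),
        "sparse": dict(
            n_compounds=150, probe_fraction=0.18, active_fraction_range=(0.03, 0.18)
        ),
    }
    if name not in presets:
        raise ValueError(f"unknown reference config {name!r}; options: {sorted(presets)}")
    fields = {**presets[name], **overrides}
    return SynthConfig(rng_seed=rng_seed, **fields)


# ---------------------------------------------------------------------------
# sequences

def _scrub_motifs(seq: list[str], motifs: Sequence[str], rng: np.random.Generator) -> None:
    """Mutate letters in place until no motif occurs in the sequence."""
    k = len(motifs[0])
    text = "".join(seq)
    guard = 0
    while True:
        hit = next((m for m in motifs if m in text), None)
        if hit is None:
            return
        pos = text.index(hit)
        seq[pos] = rng.choice([a for a in AA_ALPHABET if a != seq[pos]])
        text = "".join(seq)
        guard += 1
        if guard > 10_000:  # pragma: no cover
            raise RuntimeError("motif scrubbing did not converge")


def _draw_distinct_motifs(n: int, k: int, rng, taken: set[str]) -> list[str]:
    letters = np.array(list(AA_ALPHABET))
    out: list[str] = []
    while len(out) < n:
        m = "".join(rng.choice(letters, size=k))
        if m not in taken:
            taken.add(m)
            out.append(m)
    return out


def _build_sequence(
    L: int,
    sig: str,
    unique_motif: str,
    own_group_motif: str,
    other_group_motifs: Sequence[str],
    copies: int,
    enrichment: float,
    rng,
) -> str:
    """One sequence as a shuffled bag of tokens.

    Tokens: the target's unique motif (once), its group motif (``copies``
    times), the *constituent dipeptides* of every other group's motif
    (``copies`` times each, as camouflage so dipeptide counts carry little
    group information), and signature-enriched filler letters up to length L.
    """
    tokens = [unique_motif] + [own_group_motif] * copies
    for m in other_group_motifs:
        tokens.extend([m[:2]] * copies)
        tokens.extend([m[1:]] * copies)
    planted = sum(len(t) for t in tokens)
    n_filler = max(L - planted, 0)
    probs = np.full(len(AA_ALPHABET), (1 - enrichment) / (len(AA_ALPHABET) - 1))
    probs[AA_ALPHABET.index(sig)] = enrichment
    tokens.extend(rng.choice(list(AA_ALPHABET), size=n_filler, p=probs))
    order = rng.permutation(len(tokens))
    return "".join(tokens[i] for i in order)


def _make_sequences(
    config: SynthConfig, target_ids: Sequence[str], groups: dict[str, int], rng
) -> tuple[dict[str, str], dict[str, str], dict[int, str]]:
    """Sequences with three layers of target-block signal.

    1. Group signature letter enrichment (letter / dipeptide-level signal).
    2. Group motifs: a tripeptide planted ``group_motif_copies`` times in
       every member, absent elsewhere, with dipeptide camouflage (crisp
       trigram-level group signal).
    3. One unique motif per target (family-wide unique marker).
    """
    k = config.motif_length
    copies = config.group_motif_copies
    n_groups = max(groups.values()) + 1
    for _ in range(200):
        taken: set[str] = set()
        unique = _draw_distinct_motifs(len(target_ids), k, rng, taken)
        group_motifs = _draw_distinct_motifs(n_groups, k, rng, taken)
        unique_of = dict(zip(target_ids, unique))
        seqs: dict[str, list[str]] = {}
        for tid in target_ids:
            g = groups[tid]
            L = int(rng.integers(*config.sequence_length_range))
            text = _build_sequence(
                L,
                SIGNATURE_LETTERS[g],
                unique_of[tid],
                group_motifs[g],
                [m for j, m in enumerate(group_motifs) if j != g],
                copies,
                config.signature_enrichment,
                rng,
            )
            seqs[tid] = list(text)
        # destroy accidental occurrences of motifs where they do not belong
        for tid in target_ids:
            g = groups[tid]
            forbidden = [m for t, m in unique_of.items() if t != tid]
            forbidden += [m for j, m in enumerate(group_motifs) if j != g]
            _scrub_motifs(seqs[tid], forbidden, rng)
        final = {tid: "".join(s) for tid, s in seqs.items()}
        unique_ok = all(
            sum(s.count(m) for s in final.values()) == 1
            for m in unique_of.values()
        )
        group_ok = all(
            final[tid].count(group_motifs[groups[tid]]) >= max(1, copies - 1)
            for tid in target_ids
        )
        if unique_ok and group_ok:
            motif_map = {g: m for g, m in enumerate(group_motifs)}
            return final, unique_of, motif_map
    raise RuntimeError("could not plant unique motifs; relax the configuration")


# ---------------------------------------------------------------------------
# compounds

def _random_smiles(rng: np.random.Generator) -> str:
    from rdkit import Chem

    while True:
        n = int(rng.integers(2, 7))
        body = "".join(rng.choice(_FRAGMENTS, size=n))
        smiles = body + str(rng.choice(_TERMINALS))
        if Chem.MolFromSmiles(smiles) is not None:
            return smiles


def _smiles_raw_features(smiles_list: Sequence[str]) -> np.ndarray:
    from .descriptors import PCHEM_FEATURE_NAMES, pchem_block

    idx = [PCHEM_FEATURE_NAMES.index(f"pchem:{n}") for n in _SMILES_RULE_DESCRIPTORS]
    return np.vstack([pchem_block(s).values[idx] for s in smiles_list])


# ---------------------------------------------------------------------------
# labels and Ki back-generation

def _rule_label(x: np.ndarray, feature: int, threshold: float, potency_weight: float) -> int:
    """Active iff potency (feature 0, shared by all targets) plus the
    target's group feature exceeds the target's threshold."""
    return int(potency_weight * x[0] + x[feature] > threshold)


def _back_generate_kis(labels: Sequence[int], rng) -> np.ndarray:
    """Ki values whose per-target auto-derived scheme reproduces the labels.

    Actives get Ki in (5, 50], inactives in [1500, 1600].  If the resulting
    mean exceeds 1500 nM (so the derived inactive threshold would rise above
    some inactive Ki values), inactive values are shrunk toward 1500 until
    every label survives the round trip.
    """
    labels = np.asarray(labels, dtype=int)
    kis = np.where(
        labels == 1,
        rng.uniform(5.0, 50.0, size=len(labels)),
        rng.uniform(1500.0, 1600.0, size=len(labels)),
    )
    if not labels.any():
        kis[:] = 1500.0
        return kis
    for _ in range(60):
        if kis.mean() <= 1500.0:
            return kis
        mask = labels == 0
        kis[mask] = 1500.0 + (kis[mask] - 1500.0) * 0.5
    kis[labels == 0] = 1500.0
    return kis


def _direct_probe_count(rows: pd.DataFrame) -> set[str]:
    """Probe predicate by direct counting (independent of split_probes)."""
    actives = Counter(rows.loc[rows["label"] == ACTIVE, "compound_id"])
    inactives = Counter(rows.loc[rows["label"] == INACTIVE, "compound_id"])
    compounds = set(rows["compound_id"])
    return {
        c for c in compounds if actives.get(c, 0) == 1 and inactives.get(c, 0) >= 1
    }


# ---------------------------------------------------------------------------
# main entry points

def generate(config: SynthConfig) -> SynthDataset:
    """Generate a full synthetic dataset (deterministic in ``config.rng_seed``)."""
    rng = np.random.default_rng(config.rng_seed)
    target_ids = [f"T{i}" for i in range(config.n_targets)]
    groups = {tid: i % config.n_groups for i, tid in enumerate(target_ids)}
    sequences, motifs, group_motifs = _make_sequences(config, target_ids, groups, rng)

    # per-target active fractions: group base levels spread over the range,
    # plus a per-target jitter, so group-mates share similar rules
    lo, hi = config.active_fraction_range
    bases = np.linspace(lo, hi, config.n_groups)
    fractions = {}
    for tid in target_ids:
        f = bases[groups[tid]] + rng.uniform(
            -config.group_fraction_jitter, config.group_fraction_jitter
        )
        fractions[tid] = float(np.clip(f, lo, hi))

    ids = [f"C{i:05d}" for i in range(config.n_compounds)]
    scaler = None
    if config.smiles:
        smiles = {cid: _random_smiles(rng) for cid in ids}
        raw = _smiles_raw_features([smiles[c] for c in ids])
        mu, sd = raw.mean(axis=0), raw.std(axis=0)
        sd[sd == 0] = 1.0
        scaler = (mu, sd)
        X = (raw - mu) / sd
        features = {cid: X[i] for i, cid in enumerate(ids)}
    else:
        smiles = {cid: "" for cid in ids}
        features = {cid: rng.standard_normal(config.n_chemical_features) for cid in ids}
        X = np.vstack([features[c] for c in ids])

    w_pot = config.potency_weight
    rule_feature = {tid: 1 + groups[tid] for tid in target_ids}
    rule_threshold = {
        tid: float(
            np.quantile(
                w_pot * X[:, 0] + X[:, rule_feature[tid]], 1.0 - fractions[tid]
            )
        )
        for tid in target_ids
    }

    truth = GroundTruth(
        group_of=groups,
        signature_letters={g: SIGNATURE_LETTERS[g] for g in range(config.n_groups)},
        planted_motifs=motifs,
        group_motifs=group_motifs,
        rule_feature=rule_feature,
        rule_threshold=rule_threshold,
        potency_weight=w_pot,
        target_active_fraction=fractions,
    )

    # Each compound annotates targets of one "home" group preferentially, so
    # its profile is label-correlated (mostly-active or mostly-inactive
    # compounds dominate, keeping accidental probes a small minority).
    group_sizes = np.bincount(list(groups.values()), minlength=config.n_groups)
    rows: list[tuple[str, str, str]] = []
    for cid in ids:
        home = int(rng.integers(config.n_groups))
        b = config.home_group_bias
        w = np.array([b if groups[t] == home else 0.25 for t in target_ids])
        probs = np.minimum(config.annotation_density * w * len(w) / w.sum(), 1.0)
        mask = rng.random(config.n_targets) < probs
        for tid, annotate in zip(target_ids, mask):
            if not annotate:
                continue
            label = _rule_label(
                features[cid], rule_feature[tid], rule_threshold[tid], w_pot
            )
            if rng.random() < config.noise_rate:
                label = 1 - label
                truth.noise_flips.add((cid, tid))
            rows.append((cid, tid, ACTIVE if label else INACTIVE))

    dataset = SynthDataset(
        config=config,
        records=[],
        annotations=AnnotationTable.from_records(rows),
        sequences=sequences,
        compound_features=features,
        smiles=smiles,
        truth=truth,
        feature_scaler=scaler,
    )

    n_probes = int(round(config.probe_fraction * config.n_compounds))
    if n_probes:
        dataset = make_probe_compounds(dataset, n_probes, rng)

    dataset.records = _records_from_annotations(dataset, rng)
    dataset.truth.probe_compounds = _direct_probe_count(dataset.annotations.rows)
    return dataset


def make_probe_compounds(
    dataset: SynthDataset, n_probes: int, rng: np.random.Generator | None = None
) -> SynthDataset:
    """Add ``n_probes`` compounds whose annotation profiles satisfy the probe rule.

    Each added compound gets exactly one active annotation (on a target its
    ground-truth rule activates) and one to three inactive annotations; no
    label noise is applied to planted probes.
    """
    if n_probes == 0:
        return dataset
    config = dataset.config
    rng = rng if rng is not None else np.random.default_rng(config.rng_seed + 1)
    truth = dataset.truth
    target_ids = sorted(truth.rule_feature)
    new_rows: list[tuple[str, str, str]] = []
    start = len(dataset.compound_features)
    made = 0
    attempts = 0
    while made < n_probes:
        attempts += 1
        if attempts > 200 * n_probes:
            raise ValueError(
                f"could not generate {n_probes} probe compounds; only {made} feasible "
                "(probe fraction unreachable under the configured rules)"
            )
        cid = f"C{start + made:05d}"
        if config.smiles:
            candidate_smiles = _random_smiles(rng)
            mu, sd = dataset.feature_scaler
            x = (_smiles_raw_features([candidate_smiles])[0] - mu) / sd
        else:
            candidate_smiles = ""
            x = rng.standard_normal(config.n_chemical_features)
        labels = {
            tid: _rule_label(
                x, truth.rule_feature[tid], truth.rule_threshold[tid], truth.potency_weight
            )
            for tid in target_ids
        }
        active_targets = [t for t, v in labels.items() if v == 1]
        inactive_targets = [t for t, v in labels.items() if v == 0]
        if not active_targets or not inactive_targets:
            continue
        chosen_active = str(rng.choice(active_targets))
        n_inactive = int(rng.integers(1, min(3, len(inactive_targets)) + 1))
        chosen_inactive = list(
            rng.choice(inactive_targets, size=n_inactive, replace=False)
        )
        dataset.compound_features[cid] = x
        dataset.smiles[cid] = candidate_smiles
        new_rows.append((cid, chosen_active, ACTIVE))
        new_rows.extend((cid, t, INACTIVE) for t in chosen_inactive)
        truth.planted_probes.add(cid)
        made += 1
    combined = pd.concat(
        [dataset.annotations.rows, pd.DataFrame(new_rows, columns=list(AnnotationTable.COLUMNS))],
        ignore_index=True,
    )
    dataset.annotations = AnnotationTable(combined)
    return dataset


def _records_from_annotations(dataset: SynthDataset, rng) -> list[BioactivityRecord]:
    """Back-generate per-target Ki values consistent with the labels."""
    records: list[BioactivityRecord] = []
    rows = dataset.annotations.rows
    for tid, sub in rows.groupby("target_id", sort=True):
        labels = (sub["label"] == ACTIVE).astype(int).to_numpy()
        kis = _back_generate_kis(labels, rng)
        for (_, row), ki in zip(sub.iterrows(), kis):
            records.append(
                BioactivityRecord(
                    compound_id=row["compound_id"],
                    smiles=dataset.smiles.get(row["compound_id"], ""),
                    target_id=tid,
                    ki_nm=float(ki),
                )
            )
    return records
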