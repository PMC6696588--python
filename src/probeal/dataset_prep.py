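"""Ki discretization and the probe / non-probe compound split.

Raw inhibition-constant records are discretized per target with a 30-fold
separated threshold pair derived from the per-target mean Ki, and compounds
are then partitioned into *probe* compounds (exactly one active annotation
and at least one inactive annotation — held out as the external prediction
set) and *non-probe* compounds (the training pool).

Threshold rule.  For a target with mean Ki m (nM):

    inactive_threshold = max(m, 1500)        # weak means are kept as-is,
                                             # strong means are raised to 1500
    active_threshold   = round(inactive_threshold / 30)   # nearest integer nM

A record is inactive when Ki >= inactive_threshold, active when
Ki <= active_threshold, and dropped when it falls strictly inside the
indeterminate zone between the two.  The re-adjustment of means below
1500 nM keeps the active boundary practical (never stricter than 50 nM);
a mean of 1803 nM therefore yields the 1803/60 pair while any mean at or
below 1500 yields 1500/50.
"""

from __future__ import annotations

import json
import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "BioactivityRecord",
    "DiscretizationScheme",
    "AnnotationTable",
    "ProbeSplit",
    "FilterReport",
    "derive_thresholds",
    "discretize",
    "apply_retention_filters",
    "split_probes",
    "prepare_dataset",
    "read_bioactivity_table",
    "read_fasta",
    "write_fasta",
]

INACTIVE_CAP_NM = 1500.0
ACTIVE_FOLD = 30.0
MIN_COMPOUNDS_PRE = 50
MIN_COMPOUNDS_POST = 30

ACTIVE = "active"
INACTIVE = "inactive"


@dataclass(frozen=True)
class BioactivityRecord:
    """One (compound, target, Ki) measurement."""

    compound_id: str
    smiles: str
    target_id: str
    ki_nm: float

    def __post_init__(self):
        if not self.ki_nm > 0:
            raise ValueError(
                f"Ki must be positive, got {self.ki_nm} for "
                f"({self.compound_id}, {self.target_id})"
            )


@dataclass(frozen=True)
class DiscretizationScheme:
    """Per-target inactive/active Ki thresholds (nM) and retention status."""

    target_id: str
    inactive_threshold_nm: float
    active_threshold_nm: float
    retained: bool = True
    n_classified: int = 0

    def __post_init__(self):
        if self.active_threshold_nm > self.inactive_threshold_nm:
            raise ValueError("active threshold cannot exceed inactive threshold")


def derive_thresholds(
    ki_values: Sequence[float], target_id: str = ""
) -> DiscretizationScheme:
    """Derive the (inactive, active) threshold pair for one target.

    The inactive boundary is the mean Ki, re-adjusted up to 1500 nM when the
    mean is stronger (numerically smaller) than 1500 nM; the active boundary
    is a 30-fold stronger Ki, rounded to the nearest integer nM.
    """
    values = np.asarray(list(ki_values), dtype=float)
    if values.size == 0:
        raise ValueError(f"no Ki data for target {target_id!r}")
    if np.any(values <= 0):
        raise ValueError(f"non-positive Ki for target {target_id!r}")
    mean = float(values.mean())
    inactive = max(mean, INACTIVE_CAP_NM)
    active = float(round(inactive / ACTIVE_FOLD))
    return DiscretizationScheme(
        target_id=target_id, inactive_threshold_nm=inactive, active_threshold_nm=active
    )


@dataclass
class AnnotationTable:
    """Discretized (compound, target, label) rows; at most one row per pair."""

    rows: pd.DataFrame  # columns: compound_id, target_id, label

    COLUMNS = ("compound_id", "target_id", "label")

    def __post_init__(self):
        df = self.rows
        missing = set(self.COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"annotation table missing columns {sorted(missing)}")
        if df.duplicated(subset=["compound_id", "target_id"]).any():
            raise ValueError("duplicate (compound, target) annotation")
        bad = set(df["label"]) - {ACTIVE, INACTIVE}
        if bad:
            raise ValueError(f"unknown labels {sorted(bad)}")
        self.rows = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.rows)

    @property
    def compounds(self) -> set[str]:
        return set(self.rows["compound_id"])

    @property
    def targets(self) -> set[str]:
        return set(self.rows["target_id"])

    def profile(self, compound_id: str) -> dict[str, str]:
        sub = self.rows[self.rows["compound_id"] == compound_id]
        return dict(zip(sub["target_id"], sub["label"]))

    def label_counts(self) -> pd.DataFrame:
        """Per-compound active/inactive annotation counts."""
        pivot = (
            self.rows.groupby(["compound_id", "label"]).size().unstack(fill_value=0)
        )
        for col in (ACTIVE, INACTIVE):
            if col not in pivot.columns:
                pivot[col] = 0
        return pivot[[ACTIVE, INACTIVE]]

    def subset(self, compound_ids: Iterable[str]) -> "AnnotationTable":
        ids = set(compound_ids)
        return AnnotationTable(
            self.rows[self.rows["compound_id"].isin(ids)].reset_index(drop=True)
        )

    def to_csv(self, path: str | Path, sep: str = "\t") -> None:
        self.rows.to_csv(path, sep=sep, index=False)

    @classmethod
    def from_records(
        cls, records: Iterable[tuple[str, str, str]]
    ) -> "AnnotationTable":
        return cls(
            pd.DataFrame(records, columns=list(cls.COLUMNS))
        )

    @classmethod
    def read_csv(cls, path: str | Path) -> "AnnotationTable":
        return cls(pd.read_csv(path, sep=_sep_for(path)))


def discretize(
    records: Iterable[BioactivityRecord], scheme: DiscretizationScheme
) -> AnnotationTable:
    """Label one target's records against its scheme; indeterminate Ki is dropped."""
    rows = []
    n_dropped = 0
    for rec in records:
        if rec.target_id != scheme.target_id:
            raise ValueError(
                f"record target {rec.target_id!r} does not match scheme "
                f"{scheme.target_id!r}"
            )
        if rec.ki_nm >= scheme.inactive_threshold_nm:
            rows.append((rec.compound_id, rec.target_id, INACTIVE))
        elif rec.ki_nm <= scheme.active_threshold_nm:
            rows.append((rec.compound_id, rec.target_id, ACTIVE))
        else:
            n_dropped += 1
    if n_dropped:
        logger.info(
            "%s: %d record(s) in the indeterminate zone dropped",
            scheme.target_id,
            n_dropped,
        )
    return AnnotationTable(
        pd.DataFrame(rows, columns=list(AnnotationTable.COLUMNS))
    )


def _drop_inconsistent(
    records: Sequence[BioactivityRecord], schemes: Mapping[str, DiscretizationScheme]
) -> tuple[list[BioactivityRecord], int]:
    """Collapse duplicate (compound, target) measurements.

    Pairs whose duplicate measurements discretize to conflicting labels are
    removed entirely; consistent duplicates collapse to one representative.
    """
    by_pair: dict[tuple[str, str], list[BioactivityRecord]] = defaultdict(list)
    for rec in records:
        by_pair[(rec.compound_id, rec.target_id)].append(rec)
    kept: list[BioactivityRecord] = []
    n_conflicting = 0
    for (cid, tid), recs in by_pair.items():
        scheme = schemes[tid]
        labels = set()
        for r in recs:
            if r.ki_nm >= scheme.inactive_threshold_nm:
                labels.add(INACTIVE)
            elif r.ki_nm <= scheme.active_threshold_nm:
                labels.add(ACTIVE)
            else:
                labels.add("indeterminate")
        if len(labels) > 1:
            n_conflicting += 1
            logger.info("inconsistent measurements for (%s, %s); pair dropped", cid, tid)
            continue
        kept.append(recs[0])
    return kept, n_conflicting


def apply_retention_filters(
    records: Sequence[BioactivityRecord],
    min_pre: int = MIN_COMPOUNDS_PRE,
    min_post: int = MIN_COMPOUNDS_POST,
) -> set[str]:
    """Return target ids surviving the pre- and post-discretization size filters.

    ``min_pre`` applies to the number of distinct compounds measured against
    a target before discretization; ``min_post`` to the number of compounds
    still classified (outside the indeterminate zone) afterwards.
    """
    by_target: dict[str, list[BioactivityRecord]] = defaultdict(list)
    for rec in records:
        by_target[rec.target_id].append(rec)
    retained: set[str] = set()
    for tid, recs in by_target.items():
        n_pre = len({r.compound_id for r in recs})
        if n_pre < min_pre:
            logger.info("%s dropped: %d compound(s) < min_pre=%d", tid, n_pre, min_pre)
            continue
        scheme = derive_thresholds([r.ki_nm for r in recs], target_id=tid)
        classified = {
            r.compound_id
            for r in recs
            if r.ki_nm >= scheme.inactive_threshold_nm
            or r.ki_nm <= scheme.active_threshold_nm
        }
        if len(classified) < min_post:
            logger.info(
                "%s dropped: %d classified compound(s) < min_post=%d",
                tid,
                len(classified),
                min_post,
            )
            continue
        retained.add(tid)
    if not retained:
        logger.warning("no targets survived the retention filters")
    return retained


@dataclass
class ProbeSplit:
    """Partition of an annotation table into probe (external) and non-probe sets."""

    probe_compounds: set[str]
    nonprobe_compounds: set[str]
    probe_annotations: AnnotationTable
    nonprobe_annotations: AnnotationTable

    def __post_init__(self):
        if self.probe_compounds & self.nonprobe_compounds:
            raise ValueError("probe and non-probe compound sets overlap")


def split_probes(table: AnnotationTable) -> ProbeSplit:
    """Split compounds into probes (1 active + >=1 inactive annotation) and the rest.

    All annotations of a probe compound form the external prediction table;
    everything else is the training table.
    """
    if len(table) == 0:
        empty = AnnotationTable(pd.DataFrame(columns=list(AnnotationTable.COLUMNS)))
        return ProbeSplit(set(), set(), empty, empty)
    counts = table.label_counts()
    is_probe = (counts[ACTIVE] == 1) & (counts[INACTIVE] >= 1)
    probe_ids = set(counts.index[is_probe])
    nonprobe_ids = set(counts.index[~is_probe])
    return ProbeSplit(
        probe_compounds=probe_ids,
        nonprobe_compounds=nonprobe_ids,
        probe_annotations=table.subset(probe_ids),
        nonprobe_annotations=table.subset(nonprobe_ids),
    )


@dataclass
class FilterReport:
    """Counts of what was dropped at each preparation stage."""

    n_records_raw: int = 0
    n_targets_raw: int = 0
    n_targets_retained: int = 0
    n_pairs_inconsistent: int = 0
    n_records_indeterminate: int = 0
    n_annotations: int = 0
    n_probe_compounds: int = 0
    n_nonprobe_compounds: int = 0
    per_target: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2, sort_keys=True))


def prepare_dataset(
    records: Sequence[BioactivityRecord],
    min_pre: int = MIN_COMPOUNDS_PRE,
    min_post: int = MIN_COMPOUNDS_POST,
) -> tuple[ProbeSplit, dict[str, DiscretizationScheme], FilterReport]:
    """Full preparation pass: filters, discretization and the probe split."""
    report = FilterReport(
        n_records_raw=len(records),
        n_targets_raw=len({r.target_id for r in records}),
    )
    retained = apply_retention_filters(records, min_pre=min_pre, min_post=min_post)
    report.n_targets_retained = len(retained)
    kept = [r for r in records if r.target_id in retained]

    schemes: dict[str, DiscretizationScheme] = {}
    by_target: dict[str, list[BioactivityRecord]] = defaultdict(list)
    for rec in kept:
        by_target[rec.target_id].append(rec)
    for tid, recs in sorted(by_target.items()):
        schemes[tid] = derive_thresholds([r.ki_nm for r in recs], target_id=tid)

    kept, n_conflicting = _drop_inconsistent(kept, schemes)
    report.n_pairs_inconsistent = n_conflicting

    frames = []
    for tid in sorted(by_target):
        recs = [r for r in kept if r.target_id == tid]
        table = discretize(recs, schemes[tid])
        n_classified = len(table)
        schemes[tid] = DiscretizationScheme(
            target_id=tid,
            inactive_threshold_nm=schemes[tid].inactive_threshold_nm,
            active_threshold_nm=schemes[tid].active_threshold_nm,
            retained=True,
            n_classified=n_classified,
        )
        report.per_target[tid] = {
            "n_records": len(recs),
            "n_classified": n_classified,
            "inactive_threshold_nm": schemes[tid].inactive_threshold_nm,
            "active_threshold_nm": schemes[tid].active_threshold_nm,
            "label_counts": dict(Counter(table.rows["label"])),
        }
        frames.append(table.rows)
    all_rows = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=list(AnnotationTable.COLUMNS))
    )
    table = AnnotationTable(all_rows)
    report.n_records_indeterminate = (
        len(kept) - len(table)
    )
    report.n_annotations = len(table)

    split = split_probes(table)
    report.n_probe_compounds = len(split.probe_compounds)
    report.n_nonprobe_compounds = len(split.nonprobe_compounds)
    return split, schemes, report


# ---------------------------------------------------------------------------
# I/O

def _sep_for(path: str | Path) -> str:
    return "," if str(path).endswith(".csv") else "\t"


def read_bioactivity_table(path: str | Path) -> list[BioactivityRecord]:
    """Read a delimited bioactivity table (.csv comma / anything else tab).

    Required columns: compound_id, smiles, target_id, ki_nm (Ki fixed in nM).
    """
    df = pd.read_csv(path, sep=_sep_for(path))
    required = {"compound_id", "smiles", "target_id", "ki_nm"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    df["smiles"] = df["smiles"].fillna("")
    return [
        BioactivityRecord(
            compound_id=str(row.compound_id),
            smiles=str(row.smiles),
            target_id=str(row.target_id),
            ki_nm=float(row.ki_nm),
        )
        for row in df.itertuples(index=False)
    ]


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an {id: sequence} mapping (order-preserving)."""
    sequences: dict[str, str] = {}
    name = None
    chunks: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                if name is not None:
                    sequences[name] = "".join(chunks)
                name = line[1:].split()[0]
                chunks = []
            else:
                if name is None:
                    raise ValueError(f"{path}: sequence data before header")
                chunks.append(line)
    if name is not None:
        sequences[name] = "".join(chunks)
    return sequences


def write_fasta(sequences: Mapping[str, str], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
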