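"""Protein sequence records, FASTA I/O, validation, labelling and splitting.

Sequences are kept as plain residue strings over the 20-letter amino-acid
alphabet. Records carrying ambiguity codes (B, J, O, U, X, Z) or any other
non-canonical symbol are parsed but rejected by :func:`validate_sequence`;
descriptor encodings are undefined for them. The minimum accepted length is
2 residues so that dipeptide-based encodings (which normalise by ``L - 1``)
are well defined.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, NamedTuple, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

#: Canonical amino-acid alphabet, alphabetical by one-letter code.
ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
ALPHABET_SET = frozenset(ALPHABET)

#: Minimum sequence length; one dipeptide must exist.
MIN_LENGTH = 2

POSITIVE, NEGATIVE = 1, 0
TRAIN, TEST = "train", "test"


class DataError(ValueError):
    """Raised for malformed or inconsistent input data."""


@dataclass(frozen=True)
class ProteinSequence:
    """A named protein sequence; residues uppercased, not yet validated."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "residues", self.residues.upper())

    def __len__(self) -> int:
        return len(self.residues)


class ValidationResult(NamedTuple):
    ok: bool
    reason: str | None


def validate_sequence(seq: ProteinSequence | str) -> ValidationResult:
    """Accept a sequence iff every residue is canonical and ``L >= 2``.

    The reason string names the first offending character (this subsumes the
    ambiguity codes B/J/O/U/X/Z) or states the length rule. Total function:
    never raises.
    """
    residues = seq.residues if isinstance(seq, ProteinSequence) else seq.upper()
    for ch in residues:
        if ch not in ALPHABET_SET:
            return ValidationResult(False, f"non-canonical residue {ch!r}")
    if len(residues) < MIN_LENGTH:
        return ValidationResult(
            False, f"length {len(residues)} < minimum {MIN_LENGTH}"
        )
    return ValidationResult(True, None)


def _open_maybe_gzip(path: Path, mode: str = "rt"):
    if str(path).endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def read_fasta(path: str | Path) -> list[ProteinSequence]:
    """Read FASTA (plain or gzipped) into :class:`ProteinSequence` records.

    Wrapped sequence lines are concatenated, residues uppercased, record
    order preserved. No validation is applied here; records with ambiguous
    residues are retained and rejected downstream by
    :func:`validate_sequence`.
    """
    path = Path(path)
    with _open_maybe_gzip(path) as handle:
        records = [
            ProteinSequence(id=rec.id, residues=str(rec.seq))
            for rec in SeqIO.parse(handle, "fasta")
        ]
    if not records:
        logger.warning("no FASTA records found in %s", path)
    return records


def write_fasta(records: Iterable[ProteinSequence], path: str | Path) -> None:
    """Write records as single-line-per-sequence FASTA (byte-stable)."""
    path = Path(path)
    seqs = [SeqRecord(Seq(r.residues), id=r.id, description="") for r in records]
    with _open_maybe_gzip(path, "wt") as handle:
        SeqIO.write(seqs, handle, "fasta-2line")


@dataclass
class LabeledDataset:
    """Sequences with binary labels and optional train/test partition tags.

    Labels are 1 for the positive class and 0 for the negative class.
    """

    sequences: list[ProteinSequence]
    labels: np.ndarray
    partition: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.sequences) != len(self.labels):
            raise DataError(
                f"{len(self.sequences)} sequences but {len(self.labels)} labels"
            )
        ids = [s.id for s in self.sequences]
        if len(set(ids)) != len(ids):
            dup = next(i for i in ids if ids.count(i) > 1)
            raise DataError(f"duplicate sequence id {dup!r}")

    def __len__(self) -> int:
        return len(self.sequences)

    def __iter__(self) -> Iterator[tuple[ProteinSequence, int]]:
        return zip(self.sequences, self.labels)

    @property
    def ids(self) -> list[str]:
        return [s.id for s in self.sequences]

    def class_indices(self, label: int) -> np.ndarray:
        return np.flatnonzero(self.labels == label)

    def subset(self, indices: Sequence[int]) -> "LabeledDataset":
        idx = np.asarray(indices, dtype=int)
        return LabeledDataset(
            sequences=[self.sequences[i] for i in idx],
            labels=self.labels[idx],
            partition={
                s.id: self.partition[s.id]
                for i in idx
                for s in [self.sequences[i]]
                if s.id in self.partition
            },
        )

    def partition_subset(self, tag: str) -> "LabeledDataset":
        idx = [i for i, s in enumerate(self.sequences) if self.partition.get(s.id) == tag]
        return self.subset(idx)

    def validate(self) -> "LabeledDataset":
        """Drop records rejected by :func:`validate_sequence`, logging each."""
        keep = []
        for i, (seq, _) in enumerate(self):
            ok, reason = validate_sequence(seq)
            if ok:
                keep.append(i)
            else:
                logger.info("excluding %s: %s", seq.id, reason)
        return self.subset(keep)

    def to_manifest(self) -> pd.DataFrame:
        """Dataset manifest: id, label, partition, length."""
        return pd.DataFrame(
            {
                "id": self.ids,
                "label": np.where(self.labels == POSITIVE, "positive", "negative"),
                "partition": [self.partition.get(i, "") for i in self.ids],
                "length": [len(s) for s in self.sequences],
            }
        )


def from_fasta_pair(
    positives_path: str | Path, negatives_path: str | Path
) -> LabeledDataset:
    """Build a dataset from one FASTA of positives and one of negatives."""
    pos = read_fasta(positives_path)
    neg = read_fasta(negatives_path)
    labels = np.concatenate([np.ones(len(pos), int), np.zeros(len(neg), int)])
    return LabeledDataset(sequences=pos + neg, labels=labels)


def from_fasta_with_labels(
    fasta_path: str | Path, label_map_path: str | Path
) -> LabeledDataset:
    """Build a dataset from one FASTA plus a TSV label map (id<TAB>label)."""
    records = read_fasta(fasta_path)
    table = pd.read_csv(label_map_path, sep="\t", header=None, names=["id", "label"])
    mapping = dict(zip(table["id"].astype(str), table["label"].astype(str)))
    labels = []
    for rec in records:
        if rec.id not in mapping:
            raise DataError(f"no label for sequence {rec.id!r}")
        lab = mapping[rec.id].lower()
        if lab not in {"positive", "negative", "1", "0"}:
            raise DataError(f"unrecognised label {lab!r} for {rec.id!r}")
        labels.append(POSITIVE if lab in {"positive", "1"} else NEGATIVE)
    return LabeledDataset(sequences=records, labels=np.array(labels))


def balanced_split(
    dataset: LabeledDataset, n_test_per_class: int, seed: int
) -> LabeledDataset:
    """Tag ``n_test_per_class`` records of each class as test, the rest train.

    Test records are drawn uniformly at random per class under ``seed``;
    the assignment is deterministic for a fixed seed. Record order is
    unchanged.
    """
    rng = np.random.default_rng(seed)
    partition: dict[str, str] = {}
    for label, name in ((POSITIVE, "positive"), (NEGATIVE, "negative")):
        idx = dataset.class_indices(label)
        if len(idx) < n_test_per_class:
            raise DataError(
                f"{name} class has {len(idx)} members, "
                f"fewer than n_test_per_class={n_test_per_class}"
            )
        test_idx = set(rng.choice(idx, size=n_test_per_class, replace=False).tolist())
        for i in idx:
            partition[dataset.sequences[i].id] = TEST if i in test_idx else TRAIN
    return replace(dataset, partition=partition)


def subsample_negatives(pool: LabeledDataset, n: int, seed: int) -> LabeledDataset:
    """Retain a uniform random subset of ``n`` negatives; positives untouched."""
    neg_idx = pool.class_indices(NEGATIVE)
    if n > len(neg_idx):
        raise DataError(f"requested {n} negatives but pool holds {len(neg_idx)}")
    rng = np.random.default_rng(seed)
    chosen = set(rng.choice(neg_idx, size=n, replace=False).tolist())
    keep = [
        i
        for i in range(len(pool))
        if pool.labels[i] == POSITIVE or i in chosen
    ]
    return pool.subset(keep)
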