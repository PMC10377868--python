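"""Fixed-dimension numeric encodings of protein sequences.

Four descriptor families are provided, each as a scikit-learn transformer
over lists of residue strings (or :class:`~hbpred.sequences.ProteinSequence`
records):

``AACEncoder`` (20)
    Amino-acid composition: residue frequencies ``N_R / L``.
``DCEncoder`` (400)
    Dipeptide composition: overlapping adjacent-pair frequencies
    ``N_{ab} / (L - 1)``.
``DDEEncoder`` (400)
    Dipeptide deviation from expected mean: a Z-score of the observed
    dipeptide frequency against a theoretical mean derived from
    synonymous-codon degeneracy under the standard genetic code (61 sense
    codons). For dipeptide ``ab``::

        TF(ab)  = (C_a / 61) * (C_b / 61)
        TV(ab)  = TF(ab) * (1 - TF(ab)) / (L - 1)
        DDE(ab) = (F(ab) - TF(ab)) / sqrt(TV(ab))

    where ``C_a`` is the number of synonymous codons of residue ``a``.
``CTDCEncoder`` / ``CTDTEncoder`` / ``CTDDEncoder`` / ``CTDEncoder``
    (39 / 39 / 195 / 273) Composition, transition and distribution over
    3-group partitions of the alphabet under 13 physicochemical properties
    (hydrophobicity under seven scales, van der Waals volume, polarity,
    polarizability, charge, secondary structure, solvent accessibility).
    C: per-group residue fractions. T: adjacent-pair between-group
    transition frequencies for the three unordered group pairs,
    normalised by ``L - 1``. D: the 1-based sequence position (as a
    percentage of ``L``) at which the running count of group members
    reaches 1%, 25%, 50%, 75% and 100% of the group's total, with the
    target count floored to an integer and clamped to a minimum of 1;
    groups absent from the sequence report 0 for all five percentiles.

All transformers are stateless (``fit`` only validates); encodings depend
only on the residue string. Feature orders are fixed and canonical: AAC
alphabetical; DC/DDE row-major over alphabetical pairs (AA, AC, ..., YY);
CTD by property-catalogue order, then group index, then percentile.
"""

from __future__ import annotations

from functools import lru_cache
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .sequences import (
    ALPHABET,
    DataError,
    LabeledDataset,
    ProteinSequence,
    validate_sequence,
)

#: Synonymous-codon counts per amino acid under the standard genetic code;
#: the 61 sense codons distribute as below (3 stop codons excluded).
CODON_DEGENERACY: dict[str, int] = {
    "A": 4, "C": 2, "D": 2, "E": 2, "F": 2, "G": 4, "H": 2, "I": 3,
    "K": 2, "L": 6, "M": 1, "N": 2, "P": 4, "Q": 2, "R": 6, "S": 6,
    "T": 4, "V": 4, "W": 1, "Y": 2,
}
N_SENSE_CODONS = 61

_INDEX = {aa: i for i, aa in enumerate(ALPHABET)}
DIPEPTIDES = [a + b for a in ALPHABET for b in ALPHABET]

DISTRIBUTION_PERCENTILES = (1, 25, 50, 75, 100)


@lru_cache(maxsize=None)
def load_property_partitions(path: str | None = None) -> pd.DataFrame:
    """Load the CTD property catalogue (property, group, residue set).

    The bundled catalogue carries 13 properties, each partitioning the 20
    amino acids into 3 disjoint groups (39 groups total). A user catalogue
    with the same TSV columns (property, group, comma-separated residues)
    may be supplied via ``path``.
    """
    if path is None:
        source = resources.files("hbpred.data").joinpath("ctd_groups.tsv")
        with resources.as_file(source) as p:
            table = pd.read_csv(p, sep="\t")
    else:
        table = pd.read_csv(Path(path), sep="\t")
    table["residues"] = table["residues"].str.replace(",", "", regex=False)
    for prop, sub in table.groupby("property", sort=False):
        joined = "".join(sub["residues"])
        if sorted(joined) != sorted(ALPHABET):
            raise DataError(
                f"property {prop!r} groups do not partition the alphabet"
            )
    return table


def _property_names(table: pd.DataFrame) -> list[str]:
    return list(dict.fromkeys(table["property"]))


def _group_masks(table: pd.DataFrame) -> np.ndarray:
    """Boolean (n_properties, 3, 20) membership masks in catalogue order."""
    props = _property_names(table)
    masks = np.zeros((len(props), 3, len(ALPHABET)), dtype=bool)
    for p, prop in enumerate(props):
        sub = table[table["property"] == prop]
        for _, row in sub.iterrows():
            for aa in row["residues"]:
                masks[p, int(row["group"]) - 1, _INDEX[aa]] = True
    return masks


def _as_residues(seq: ProteinSequence | str) -> str:
    return seq.residues if isinstance(seq, ProteinSequence) else seq.upper()


def _encode_indices(residues: str) -> np.ndarray:
    try:
        return np.array([_INDEX[ch] for ch in residues], dtype=np.intp)
    except KeyError as exc:
        raise DataError(f"non-canonical residue {exc.args[0]!r}") from None


class _SequenceEncoder(TransformerMixin, BaseEstimator):
    """Base class: stateless sequence-to-vector transformer."""

    #: minimum residues required by the encoding
    _min_length = 1

    def fit(self, X, y=None):
        self.n_features_in_ = 1
        self.feature_names_ = self.get_feature_names_out()
        return self

    def get_feature_names_out(self, input_features=None) -> np.ndarray:
        raise NotImplementedError

    def _encode_one(self, idx: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def transform(self, X) -> np.ndarray:
        rows = []
        for item in X:
            residues = _as_residues(item)
            ok, reason = validate_sequence(residues)
            if not ok or len(residues) < self._min_length:
                name = item.id if isinstance(item, ProteinSequence) else residues[:12]
                raise DataError(f"cannot encode record {name!r}: {reason}")
            rows.append(self._encode_one(_encode_indices(residues)))
        names = self.get_feature_names_out()
        if not rows:
            return np.empty((0, len(names)))
        return np.vstack(rows)

    def encode(self, seq: ProteinSequence | str) -> np.ndarray:
        """Encode a single sequence to a 1-D feature vector."""
        return self.transform([seq])[0]


class AACEncoder(_SequenceEncoder):
    """Amino-acid composition: 20 residue frequencies summing to 1."""

    def get_feature_names_out(self, input_features=None) -> np.ndarray:
        return np.array(list(ALPHABET), dtype=object)

    def _encode_one(self, idx: np.ndarray) -> np.ndarray:
        counts = np.bincount(idx, minlength=20).astype(float)
        return counts / len(idx)


class DCEncoder(_SequenceEncoder):
    """Dipeptide composition: 400 overlapping-pair frequencies summing to 1."""

    _min_length = 2

    def get_feature_names_out(self, input_features=None) -> np.ndarray:
        return np.array(DIPEPTIDES, dtype=object)

    @staticmethod
    def _dipeptide_counts(idx: np.ndarray) -> np.ndarray:
        pair_codes = idx[:-1] * 20 + idx[1:]
        return np.bincount(pair_codes, minlength=400).astype(float)

    def _encode_one(self, idx: np.ndarray) -> np.ndarray:
        return self._dipeptide_counts(idx) / (len(idx) - 1)


class DDEEncoder(_SequenceEncoder):
    """Dipeptide deviation from expected mean: 400 codon-degeneracy Z-scores."""

    _min_length = 2

    def __init__(self) -> None:
        degeneracy = np.array([CODON_DEGENERACY[a] for a in ALPHABET], float)
        frac = degeneracy / N_SENSE_CODONS
        # theoretical mean per dipeptide, row-major (front residue major)
        self._tf = np.outer(frac, frac).ravel()

    def get_feature_names_out(self, input_features=None) -> np.ndarray:
        return np.array(DIPEPTIDES, dtype=object)

    def _encode_one(self, idx: np.ndarray) -> np.ndarray:
        freq = DCEncoder._dipeptide_counts(idx) / (len(idx) - 1)
        tv = self._tf * (1.0 - self._tf) / (len(idx) - 1)
        return (freq - self._tf) / np.sqrt(tv)


class _CTDBase(_SequenceEncoder):
    """Shared catalogue handling for the CTD family."""

    def __init__(self, catalogue: str | None = None) -> None:
        self.catalogue = catalogue

    @property
    def _table(self) -> pd.DataFrame:
        return load_property_partitions(self.catalogue)

    @property
    def _props(self) -> list[str]:
        return _property_names(self._table)

    @property
    def _masks(self) -> np.ndarray:
        return _group_masks(self._table)


class CTDCEncoder(_CTDBase):
    """CTD composition: 39 per-group residue fractions (13 properties x 3)."""

    def get_feature_names_out(self, input_features=None) -> np.ndarray:
        return np.array(
            [f"{p}.G{g}" for p in self._props for g in (1, 2, 3)], dtype=object
        )

    def _encode_one(self, idx: np.ndarray) -> np.ndarray:
        counts = np.bincount(idx, minlength=20)
        # (props, 3, 20) @ (20,) -> per-group residue counts
        group_counts = self._masks @ counts
        return (group_counts / len(idx)).ravel()


class CTDTEncoder(_CTDBase):
    """CTD transition: 39 between-group adjacent-pair frequencies.

    For each property the three unordered group pairs (G1,G2), (G1,G3),
    (G2,G3) are counted over all ``L - 1`` adjacent positions, in either
    order, and normalised by ``L - 1``.
    """

    _min_length = 2
    _PAIRS = ((0, 1), (0, 2), (1, 2))

    def get_feature_names_out(self, input_features=None) -> np.ndarray:
        return np.array(
            [f"{p}.T{a + 1}{b + 1}" for p in self._props for a, b in self._PAIRS],
            dtype=object,
        )

    def _encode_one(self, idx: np.ndarray) -> np.ndarray:
        masks = self._masks
        # group id of each residue per property: (props, L)
        group_of = np.argmax(masks[:, :, idx], axis=1)
        left, right = group_of[:, :-1], group_of[:, 1:]
        out = np.empty((masks.shape[0], 3))
        for k, (a, b) in enumerate(self._PAIRS):
            out[:, k] = np.sum(
                ((left == a) & (right == b)) | ((left == b) & (right == a)), axis=1
            )
        return (out / (len(idx) - 1)).ravel()


class CTDDEncoder(_CTDBase):
    """CTD distribution: 195 percentile positions of group occurrences.

    For each of the 39 groups and each percentile p in {1,25,50,75,100}:
    the 1-based position at which the running count of group members
    reaches ``max(1, floor(p * n / 100))`` occurrences (n = total members
    of the group in the sequence), expressed as position / L * 100. Groups
    with no members report 0 for all five percentiles.
    """

    def get_feature_names_out(self, input_features=None) -> np.ndarray:
        return np.array(
            [
                f"{p}.G{g}.P{pc}"
                for p in self._props
                for g in (1, 2, 3)
                for pc in DISTRIBUTION_PERCENTILES
            ],
            dtype=object,
        )

    def _encode_one(self, idx: np.ndarray) -> np.ndarray:
        L = len(idx)
        masks = self._masks
        out = np.zeros((masks.shape[0], 3, len(DISTRIBUTION_PERCENTILES)))
        for p in range(masks.shape[0]):
            for g in range(3):
                positions = np.flatnonzero(masks[p, g, idx])  # 0-based
                n = len(positions)
                if n == 0:
                    continue
                for k, pct in enumerate(DISTRIBUTION_PERCENTILES):
                    target = max(1, (pct * n) // 100)
                    out[p, g, k] = (positions[target - 1] + 1) / L * 100.0
        return out.ravel()


class CTDEncoder(_CTDBase):
    """Concatenated CTD vector: [composition | transition | distribution], 273-dim."""

    _min_length = 2

    def __init__(self, catalogue: str | None = None) -> None:
        super().__init__(catalogue)
        self._parts = (
            CTDCEncoder(catalogue),
            CTDTEncoder(catalogue),
            CTDDEncoder(catalogue),
        )

    def get_feature_names_out(self, input_features=None) -> np.ndarray:
        return np.concatenate([p.get_feature_names_out() for p in self._parts])

    def _encode_one(self, idx: np.ndarray) -> np.ndarray:
        return np.concatenate([p._encode_one(idx) for p in self._parts])


ENCODERS: dict[str, type[_SequenceEncoder]] = {
    "aac": AACEncoder,
    "dc": DCEncoder,
    "dde": DDEEncoder,
    "ctdc": CTDCEncoder,
    "ctdt": CTDTEncoder,
    "ctdd": CTDDEncoder,
    "ctd": CTDEncoder,
}

#: Fixed output dimension per descriptor.
DIMENSIONS = {
    "aac": 20, "dc": 400, "dde": 400,
    "ctdc": 39, "ctdt": 39, "ctdd": 195, "ctd": 273,
}


def get_encoder(descriptor: str) -> _SequenceEncoder:
    """Instantiate the encoder for a descriptor name (case-insensitive)."""
    key = descriptor.lower()
    if key not in ENCODERS:
        raise DataError(
            f"unknown descriptor {descriptor!r}; choose from {sorted(ENCODERS)}"
        )
    return ENCODERS[key]()


def encode_dataset(dataset: LabeledDataset, descriptor: str) -> pd.DataFrame:
    """Encode every sequence of a dataset into a named feature matrix.

    Rows follow dataset order (index = sequence ids); a ``label`` column is
    carried alongside the descriptor columns. Unvalidated sequences raise a
    :class:`DataError` naming the record.
    """
    encoder = get_encoder(descriptor)
    names = encoder.get_feature_names_out()
    matrix = encoder.transform(dataset.sequences)
    frame = pd.DataFrame(matrix, columns=names, index=pd.Index(dataset.ids, name="id"))
    frame.insert(0, "label", dataset.labels)
    return frame


def split_matrix(frame: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Split an encoded frame into (X, y, feature_names)."""
    features = [c for c in frame.columns if c != "label"]
    return frame[features].to_numpy(float), frame["label"].to_numpy(int), features
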