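"""Feature encoders for cysteine-centered peptide windows.

Three encoding schemes turn a 21-residue window into a numeric vector.  The
central cysteine is invariant across all windows and is always excluded, so
the 20 flanking positions (-10..-1, +1..+10, in that order) carry the
features:

``binary``
    Orthogonal one-hot encoding over the 21-letter alphabet (20 amino acids
    plus the padding residue 'X'); 20 positions x 21 = 420 dimensions.

``psaap``
    Position-specific amino-acid propensity: a 21 x 20 matrix of per-position
    residue frequencies estimated from *positive* (modified) training
    windows; encoding a window looks up the propensity of its residue at
    each flanking position, giving 20 dimensions.

``aaindex``
    Physicochemical encoding: each flanking residue is replaced by 14
    property values (hydrophobicity, solvent accessibility, polarity,
    polarizability, accessible surface, alpha-amino and alpha-carboxyl pK,
    melting point, molecular weight, optical rotation, net charge index of
    side chains, entropy of formation, heat capacity, absolute entropy),
    giving 20 x 14 = 280 dimensions.  'X' contributes zeros.

The shipped property table lists one representative AAindex-style scale per
named property; see the packaged TSV.  Rows are min-max scaled to [0, 1]
over the 20 amino acids by default so heavy-unit scales (molecular weight)
do not dominate an RBF kernel.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from sulfsite.alphabet import AA_INDEX, ALPHABET, AMINO_ACIDS, PAD
from sulfsite.windowing import PeptideWindow

#: Flanking positions in feature order: upstream -10..-1 then downstream +1..+10.
FLANK_POSITIONS: tuple[int, ...] = tuple(range(-10, 0)) + tuple(range(1, 11))

N_PROPERTIES = 14
BINARY_DIM = 20 * len(ALPHABET)  # 420
PSAAP_DIM = 20
AAINDEX_DIM = 20 * N_PROPERTIES  # 280


@dataclass(frozen=True)
class PropertyTable:
    """14 physicochemical scales over the 21-letter alphabet ('X' = 0)."""

    values: pd.DataFrame  # 14 rows (properties) x 21 columns (residues)

    def __post_init__(self) -> None:
        if list(self.values.columns) != list(ALPHABET):
            raise ValueError("property table columns must be the 21-letter alphabet")
        if len(self.values) != N_PROPERTIES:
            raise ValueError(f"expected {N_PROPERTIES} property rows, got {len(self.values)}")
        if not (self.values[PAD] == 0).all():
            raise ValueError("the 'X' column must be all zeros")

    @property
    def property_names(self) -> list[str]:
        return list(self.values.index)


@dataclass(frozen=True)
class PsaapMatrix:
    """Positional residue propensities fitted on modified training windows."""

    values: pd.DataFrame  # 21 rows (residues) x 20 columns (flanking positions)

    def __post_init__(self) -> None:
        if list(self.values.index) != list(ALPHABET):
            raise ValueError("PSAAP rows must be the 21-letter alphabet")
        if list(self.values.columns) != list(FLANK_POSITIONS):
            raise ValueError("PSAAP columns must be the 20 flanking positions")
        v = self.values.to_numpy()
        if (v < 0).any() or (v > 1).any():
            raise ValueError("PSAAP entries must lie in [0, 1]")

    def to_tsv(self, path: str | Path) -> None:
        self.values.to_csv(path, sep="\t", index_label="residue")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PsaapMatrix":
        df = pd.read_csv(path, sep="\t", index_col="residue")
        df.columns = [int(c) for c in df.columns]
        return cls(df)


def load_property_table(path: str | Path) -> PropertyTable:
    """Load a property table TSV (rows: property name + 21 residue columns)."""
    df = pd.read_csv(path, sep="\t", index_col="property")
    return PropertyTable(df[list(ALPHABET)])


def load_default_property_table(normalize: bool = True) -> PropertyTable:
    """Load the packaged 14-property table, min-max scaled unless disabled."""
    ref = resources.files("sulfsite.data").joinpath("physicochemical_properties.tsv")
    with resources.as_file(ref) as path:
        table = load_property_table(path)
    return normalize_properties(table) if normalize else table


def normalize_properties(table: PropertyTable) -> PropertyTable:
    """Min-max scale each property to [0, 1] over the 20 amino acids.

    The 'X' column stays 0.  Idempotent; a property constant across all 20
    amino acids cannot be scaled and raises ``ValueError``.
    """
    df = table.values.copy().astype(float)
    aa = df[list(AMINO_ACIDS)]
    lo, hi = aa.min(axis=1), aa.max(axis=1)
    if (hi == lo).any():
        flat = df.index[hi == lo].tolist()
        raise ValueError(f"constant property rows cannot be normalized: {flat}")
    df.loc[:, list(AMINO_ACIDS)] = aa.sub(lo, axis=0).div(hi - lo, axis=0)
    df[PAD] = 0.0
    return PropertyTable(df)


def _check_window(window: PeptideWindow) -> str:
    flanks = window.flanks
    if len(flanks) != 20:
        raise ValueError("encoders require 21-residue windows (xi = eta = 10)")
    return flanks


def encode_binary(window: PeptideWindow) -> np.ndarray:
    """One-hot encode the 20 flanking residues; length 420."""
    flanks = _check_window(window)
    vec = np.zeros(BINARY_DIM)
    for j, ch in enumerate(flanks):
        vec[j * len(ALPHABET) + AA_INDEX[ch]] = 1.0
    return vec


def decode_binary(vector: np.ndarray) -> str:
    """Recover the 20 flanking residues from a one-hot vector."""
    blocks = np.asarray(vector).reshape(20, len(ALPHABET))
    if not np.array_equal(blocks.sum(axis=1), np.ones(20)):
        raise ValueError("not a valid one-hot window encoding")
    return "".join(ALPHABET[int(i)] for i in blocks.argmax(axis=1))


def fit_psaap(training_positives: Sequence[PeptideWindow]) -> PsaapMatrix:
    """Estimate per-position residue frequencies from positive windows.

    Entry (r, p) is the fraction of training positives carrying residue r at
    flanking position p; every column sums to 1.
    """
    if not training_positives:
        raise ValueError("cannot fit a PSAAP matrix from an empty collection")
    counts = np.zeros((len(ALPHABET), 20))
    for w in training_positives:
        for j, ch in enumerate(_check_window(w)):
            counts[AA_INDEX[ch], j] += 1
    freq = counts / len(training_positives)
    return PsaapMatrix(
        pd.DataFrame(freq, index=list(ALPHABET), columns=list(FLANK_POSITIONS))
    )


def encode_psaap(window: PeptideWindow, matrix: PsaapMatrix) -> np.ndarray:
    """Look up the propensity of each flanking residue; length 20."""
    flanks = _check_window(window)
    values = matrix.values.to_numpy()
    return np.array([values[AA_INDEX[ch], j] for j, ch in enumerate(flanks)])


def encode_aaindex(window: PeptideWindow, table: PropertyTable) -> np.ndarray:
    """Concatenate the 14 property values of each flanking residue; length 280."""
    flanks = _check_window(window)
    cols = table.values.to_numpy()  # 14 x 21
    return np.concatenate([cols[:, AA_INDEX[ch]] for ch in flanks])


# ---------------------------------------------------------------------------
# Stateful encoder objects used inside cross-validation, where the PSAAP
# matrix must be fitted on the training fold's positives only.
# ---------------------------------------------------------------------------

class WindowEncoder:
    """Base class: ``fit`` on training-fold positives, ``transform`` windows."""

    scheme: str
    dim: int

    def fit(self, training_positives: Sequence[PeptideWindow]) -> "WindowEncoder":
        return self

    def transform(self, windows: Sequence[PeptideWindow]) -> np.ndarray:
        raise NotImplementedError


class BinaryEncoder(WindowEncoder):
    scheme = "binary"
    dim = BINARY_DIM

    def transform(self, windows: Sequence[PeptideWindow]) -> np.ndarray:
        return np.array([encode_binary(w) for w in windows])


class PsaapEncoder(WindowEncoder):
    scheme = "psaap"
    dim = PSAAP_DIM

    def __init__(self, matrix: PsaapMatrix | None = None) -> None:
        self.matrix = matrix

    def fit(self, training_positives: Sequence[PeptideWindow]) -> "PsaapEncoder":
        self.matrix = fit_psaap(training_positives)
        return self

    def transform(self, windows: Sequence[PeptideWindow]) -> np.ndarray:
        if self.matrix is None:
            raise RuntimeError("PsaapEncoder must be fitted before transform")
        return np.array([encode_psaap(w, self.matrix) for w in windows])


class AAIndexEncoder(WindowEncoder):
    scheme = "aaindex"
    dim = AAINDEX_DIM

    def __init__(self, table: PropertyTable | None = None) -> None:
        self.table = table if table is not None else load_default_property_table()

    def transform(self, windows: Sequence[PeptideWindow]) -> np.ndarray:
        return np.array([encode_aaindex(w, self.table) for w in windows])


ENCODER_SCHEMES = ("binary", "psaap", "aaindex")


def get_encoder(scheme: str, **kwargs) -> WindowEncoder:
    """Instantiate a fresh (unfitted) encoder by scheme name."""
    if scheme == "binary":
        return BinaryEncoder()
    if scheme == "psaap":
        return PsaapEncoder(**kwargs)
    if scheme == "aaindex":
        return AAIndexEncoder(**kwargs)
    raise ValueError(f"unknown encoding scheme {scheme!r}; choose from {ENCODER_SCHEMES}")
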