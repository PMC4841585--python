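"""Cysteine-centered peptide windows and benchmark assembly.

Every candidate site is represented by a window

    P = R(-xi) ... R(-1) C R(+1) ... R(+eta)

of ``xi`` upstream and ``eta`` downstream residues around a central
cysteine; flanks that run past a protein terminus are padded with the dummy
residue ``X``.  With the default ``xi = eta = 10`` a window is a 21-mer.
Windows at experimentally modified cysteines are the positive class; every
other cysteine window from the same proteins is a negative.  A greedy
pairwise-identity filter removes near-duplicate windows before training so
homologous peptides cannot inflate cross-validation estimates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from sulfsite.alphabet import AA_INDEX, PAD, sanitize

logger = logging.getLogger(__name__)

DEFAULT_XI = 10
DEFAULT_ETA = 10
DEFAULT_IDENTITY_THRESHOLD = 0.40


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence with its accession."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"protein {self.id!r} has an empty sequence")


@dataclass(frozen=True)
class PeptideWindow:
    """A fixed-length peptide centered on a cysteine.

    ``site_position`` is the 1-based position of the central cysteine in the
    source protein; ``center_index`` is its 0-based offset inside
    ``residues`` (equal to xi).
    """

    residues: str
    center_index: int
    source_protein: str
    site_position: int

    def __post_init__(self) -> None:
        if self.residues[self.center_index] != "C":
            raise ValueError(
                f"window center must be 'C', got {self.residues[self.center_index]!r}"
            )
        bad = set(self.residues) - set(AA_INDEX)
        if bad:
            raise ValueError(f"window contains invalid characters {sorted(bad)}")
        # 'X' normally appears only as terminal padding, but may also occur
        # internally when non-standard residue codes were sanitized to 'X'.

    @property
    def flanks(self) -> str:
        """The 20 flanking residues (center cysteine excluded), in order."""
        return self.residues[: self.center_index] + self.residues[self.center_index + 1 :]

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class LabeledDataset:
    """Parallel windows and binary labels (1 = S-sulfenylated)."""

    windows: list[PeptideWindow]
    labels: list[int]

    def __post_init__(self) -> None:
        if len(self.windows) != len(self.labels):
            raise ValueError("windows and labels must have equal length")
        seen: set[tuple[str, int]] = set()
        for w in self.windows:
            key = (w.source_protein, w.site_position)
            if key in seen:
                raise ValueError(f"duplicate site {key} in dataset")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.windows)

    def __iter__(self) -> Iterator[tuple[PeptideWindow, int]]:
        return iter(zip(self.windows, self.labels))

    @property
    def positives(self) -> list[PeptideWindow]:
        return [w for w, y in zip(self.windows, self.labels) if y == 1]

    @property
    def negatives(self) -> list[PeptideWindow]:
        return [w for w, y in zip(self.windows, self.labels) if y == 0]

    def subset(self, indices: Sequence[int]) -> "LabeledDataset":
        return LabeledDataset(
            [self.windows[i] for i in indices], [self.labels[i] for i in indices]
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "accession": [w.source_protein for w in self.windows],
                "position": [w.site_position for w in self.windows],
                "window": [w.residues for w in self.windows],
                "label": self.labels,
            }
        )


def extract_windows(
    protein: ProteinRecord, xi: int = DEFAULT_XI, eta: int = DEFAULT_ETA
) -> list[PeptideWindow]:
    """Cut one window around every cysteine of ``protein``.

    Short flanks are padded with 'X' so each window has exactly ``xi``
    upstream and ``eta`` downstream characters.  A protein with no cysteine
    yields an empty list.
    """
    if xi < 1 or eta < 1:
        raise ValueError("xi and eta must be >= 1")
    seq, replaced = sanitize(protein.sequence)
    if replaced:
        logger.warning(
            "protein %s: non-standard residues %s mapped to 'X'", protein.id, replaced
        )
    windows = []
    for i, ch in enumerate(seq):
        if ch != "C":
            continue
        up = seq[max(0, i - xi) : i]
        down = seq[i + 1 : i + 1 + eta]
        residues = PAD * (xi - len(up)) + up + "C" + down + PAD * (eta - len(down))
        windows.append(
            PeptideWindow(
                residues=residues,
                center_index=xi,
                source_protein=protein.id,
                site_position=i + 1,
            )
        )
    return windows


def build_dataset(
    proteins: Iterable[ProteinRecord],
    positive_sites: Iterable[tuple[str, int]],
    xi: int = DEFAULT_XI,
    eta: int = DEFAULT_ETA,
) -> LabeledDataset:
    """Assemble the labeled benchmark from proteins and annotated sites.

    Windows at annotated cysteines are positives; all remaining cysteine
    windows from the same protein set are negatives.  Each annotated site
    must name an existing accession and point at a 'C'.
    """
    by_id = {}
    for p in proteins:
        if p.id in by_id:
            raise ValueError(f"duplicate accession {p.id!r}")
        by_id[p.id] = p
    pos = set()
    for acc, position in positive_sites:
        if acc not in by_id:
            raise KeyError(f"accession {acc!r} not found among proteins")
        seq, _ = sanitize(by_id[acc].sequence)
        if position < 1 or position > len(seq) or seq[position - 1] != "C":
            raise ValueError(
                f"site {acc}:{position} does not fall on a cysteine"
            )
        pos.add((acc, position))
    windows: list[PeptideWindow] = []
    labels: list[int] = []
    for p in by_id.values():
        for w in extract_windows(p, xi, eta):
            windows.append(w)
            labels.append(int((w.source_protein, w.site_position) in pos))
    return LabeledDataset(windows, labels)


def _window_matrix(windows: Sequence[PeptideWindow]) -> np.ndarray:
    return np.array(
        [[AA_INDEX[c] for c in w.residues] for w in windows], dtype=np.uint8
    )


def redundancy_filter(
    dataset: LabeledDataset, threshold: float = DEFAULT_IDENTITY_THRESHOLD
) -> LabeledDataset:
    """Greedily drop windows with pairwise identity >= ``threshold``.

    Identity between two equal-length windows is the fraction of positions
    carrying the same character ('X' matching 'X' counts).  The scan keeps
    the earlier window of any offending pair, CD-HIT style, so each cluster
    of near-identical peptides retains one representative.  Positives and
    negatives are filtered jointly.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    if len(dataset) == 0:
        return LabeledDataset([], [])
    mat = _window_matrix(dataset.windows)
    length = mat.shape[1]
    min_matches = threshold * length
    kept_idx: list[int] = []
    kept_rows = np.empty((len(dataset), length), dtype=np.uint8)
    n_kept = 0
    for i in range(len(dataset)):
        if n_kept:
            matches = (kept_rows[:n_kept] == mat[i]).sum(axis=1)
            if (matches >= min_matches).any():
                continue
        kept_rows[n_kept] = mat[i]
        n_kept += 1
        kept_idx.append(i)
    removed = len(dataset) - n_kept
    if removed:
        logger.info("redundancy filter removed %d of %d windows", removed, len(dataset))
    return dataset.subset(kept_idx)


# ---------------------------------------------------------------------------
# File formats: FASTA in, TSV site tables and dataset tables in/out.
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a multi-record (possibly line-wrapped) FASTA file."""
    records = [
        ProteinRecord(id=rec.id, sequence=str(rec.seq))
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def read_site_table(path: str | Path) -> pd.DataFrame:
    """Read a TSV of (accession, position, label) with 1-based positions."""
    df = pd.read_csv(path, sep="\t", dtype={"accession": str})
    required = {"accession", "position", "label"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"site table {path} lacks columns {sorted(missing)}")
    if not df["label"].isin([0, 1]).all():
        bad = df.index[~df["label"].isin([0, 1])][0] + 2  # header + 1-based
        raise ValueError(f"site table {path}: invalid label at line {bad}")
    return df


def write_site_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def write_dataset(dataset: LabeledDataset, path: str | Path) -> None:
    dataset.to_frame().to_csv(path, sep="\t", index=False)


def read_dataset(path: str | Path, xi: int = DEFAULT_XI) -> LabeledDataset:
    df = pd.read_csv(path, sep="\t", dtype={"accession": str})
    windows = [
        PeptideWindow(
            residues=row.window,
            center_index=xi,
            source_protein=row.accession,
            site_position=int(row.position),
        )
        for row in df.itertuples()
    ]
    return LabeledDataset(windows, [int(l) for l in df["label"]])
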