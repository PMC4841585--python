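"""Loader for a curated cysteine-peptide benchmark spreadsheet.

The published S-sulfenylation benchmark is distributed as a spreadsheet of
21-residue cysteine-centered peptides (modified and unmodified classes); it
is not bundled with this package and must be supplied by the user.  Sheet
and column layouts of such supplements vary, so the loader is deliberately
tolerant: it scans every sheet for a column of 21-mer peptide strings and
derives labels from an explicit 0/1 column when present, otherwise from
sheet names containing "pos"/"neg" (or "sulf"/"non").  Provenance columns
(accession, position) are picked up when recognizable; otherwise synthetic
accessions are assigned so dataset invariants hold.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path

import pandas as pd

from sulfsite.alphabet import sanitize
from sulfsite.windowing import LabeledDataset, PeptideWindow

logger = logging.getLogger(__name__)

_PEPTIDE_RE = re.compile(r"^[A-Z*]{21}$")


def _looks_like_peptide_column(series: pd.Series) -> bool:
    vals = series.dropna().astype(str).str.strip().str.upper()
    if len(vals) == 0:
        return False
    ok = vals.str.match(_PEPTIDE_RE) & (vals.str[10] == "C")
    return ok.mean() > 0.9


def _find_column(df: pd.DataFrame, keywords: tuple[str, ...]) -> str | None:
    for col in df.columns:
        if any(k in str(col).lower() for k in keywords):
            return col
    return None


def load_benchmark_xlsx(path: str | Path) -> LabeledDataset:
    """Read labeled 21-mer cysteine windows from a spreadsheet.

    Raises ``FileNotFoundError`` if the file is absent and ``ValueError``
    if no peptide column can be located.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(
            f"benchmark spreadsheet not found at {path}; supply the curated "
            "peptide table (not distributed with this package)"
        )
    sheets = pd.read_excel(path, sheet_name=None)
    windows: list[PeptideWindow] = []
    labels: list[int] = []
    counter = 0
    for sheet_name, df in sheets.items():
        pep_col = next(
            (c for c in df.columns if _looks_like_peptide_column(df[c])), None
        )
        if pep_col is None:
            continue
        label_col = _find_column(df, ("label", "class", "type"))
        acc_col = _find_column(df, ("accession", "protein", "gi", "uniprot", "id"))
        pos_col = _find_column(df, ("position", "site"))
        lower = sheet_name.lower()
        sheet_label = 1 if ("pos" in lower or "sulf" in lower and "non" not in lower) else 0
        for _, row in df.iterrows():
            raw = str(row[pep_col]).strip().upper()
            if not _PEPTIDE_RE.match(raw) or raw[10] != "C":
                continue
            seq, _ = sanitize(raw)
            counter += 1
            if label_col is not None and not pd.isna(row[label_col]):
                lab_raw = str(row[label_col]).strip().lower()
                label = 1 if lab_raw in ("1", "pos", "positive", "yes") else 0
            else:
                label = sheet_label
            acc = str(row[acc_col]) if acc_col is not None else f"PEP{counter:06d}"
            try:
                site = int(row[pos_col]) if pos_col is not None else counter
            except (TypeError, ValueError):
                site = counter
            windows.append(
                PeptideWindow(
                    residues=seq,
                    center_index=10,
                    source_protein=acc,
                    site_position=site,
                )
            )
            labels.append(label)
    if not windows:
        raise ValueError(f"no 21-mer cysteine peptide column found in {path}")
    # Provenance collisions (same accession/position in both classes or
    # malformed columns) fall back to unique synthetic keys.
    seen: set[tuple[str, int]] = set()
    for i, w in enumerate(windows):
        key = (w.source_protein, w.site_position)
        if key in seen:
            windows[i] = PeptideWindow(
                residues=w.residues,
                center_index=10,
                source_protein=f"{w.source_protein}#dup{i}",
                site_position=w.site_position,
            )
        seen.add((windows[i].source_protein, windows[i].site_position))
    logger.info(
        "loaded %d peptides (%d positive) from %s", len(windows), sum(labels), path
    )
    return LabeledDataset(windows, labels)
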