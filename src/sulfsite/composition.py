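"""Position-specific residue composition and two-sample enrichment.

Sequence-logo style analysis of cysteine-centered windows: per-position
residue frequencies within one window set, and a contrast between the
modified (positive) and unmodified (negative) sets that reports, for every
(flanking position, residue) pair, whether the residue is significantly
enriched or depleted among positives.  Padding 'X' characters are excluded
from all denominators so short flanks do not dilute frequencies.  The
contrast uses a two-proportion z-test with Fisher's exact test as the
small-count fallback, at a fixed significance threshold (default p < 0.01)
without multiple-testing correction, matching the convention of two-sample
logo tools.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from sulfsite.alphabet import AMINO_ACIDS, PAD
from sulfsite.encoders import FLANK_POSITIONS
from sulfsite.windowing import PeptideWindow

#: All 21 window positions, center included (position 0 is the cysteine).
WINDOW_POSITIONS: tuple[int, ...] = tuple(range(-10, 11))

# Expected-count threshold below which the z approximation gives way to
# Fisher's exact test.
_EXACT_FALLBACK_EXPECTED = 5.0


@dataclass(frozen=True)
class EnrichmentResult:
    position: int  # flanking index, -10..+10 excluding 0
    residue: str
    direction: str  # "enriched" (in positives) or "depleted"
    p_value: float
    positive_freq: float
    negative_freq: float


def _position_counts(windows: Sequence[PeptideWindow]) -> pd.DataFrame:
    """Residue counts per window position ('X' ignored); 21 x 20."""
    counts = pd.DataFrame(
        0, index=list(WINDOW_POSITIONS), columns=list(AMINO_ACIDS), dtype=int
    )
    for w in windows:
        for pos, ch in zip(WINDOW_POSITIONS, w.residues):
            if ch != PAD:
                counts.loc[pos, ch] += 1
    return counts


def composition_matrix(windows: Sequence[PeptideWindow]) -> pd.DataFrame:
    """Per-position residue frequencies (rows: positions -10..+10, sum to 1).

    Rows where every window carries padding (possible only off-center with
    degenerate inputs) are left as zeros.
    """
    if not windows:
        raise ValueError("composition requires at least one window")
    counts = _position_counts(windows)
    totals = counts.sum(axis=1)
    freq = counts.div(totals.replace(0, np.nan), axis=0).fillna(0.0)
    return freq


def _two_proportion_p(k1: int, n1: int, k2: int, n2: int) -> float:
    """Two-sided p for H0: equal residue frequency in the two sets.

    Pooled two-proportion z-test; Fisher's exact test when any expected
    count under the pooled rate falls below 5.  Symmetric in the two sets.
    """
    pooled = (k1 + k2) / (n1 + n2)
    expected = min(
        n1 * pooled, n1 * (1 - pooled), n2 * pooled, n2 * (1 - pooled)
    )
    if expected < _EXACT_FALLBACK_EXPECTED:
        table = [[k1, n1 - k1], [k2, n2 - k2]]
        return float(stats.fisher_exact(table, alternative="two-sided")[1])
    se = np.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
    if se == 0:
        return 1.0
    z = (k1 / n1 - k2 / n2) / se
    return float(2 * stats.norm.sf(abs(z)))


def two_sample_enrichment(
    pos_windows: Sequence[PeptideWindow],
    neg_windows: Sequence[PeptideWindow],
    alpha: float = 0.01,
) -> list[EnrichmentResult]:
    """Significant per-(position, residue) frequency differences.

    Returns one result per pair with p < ``alpha``, signed by the direction
    of the difference (enriched = more frequent among positives).  Ordered
    by position then residue.
    """
    if not pos_windows or not neg_windows:
        raise ValueError("both window collections must be non-empty")
    if not 0 < alpha <= 1:
        raise ValueError("alpha must lie in (0, 1]")
    pos_counts = _position_counts(pos_windows)
    neg_counts = _position_counts(neg_windows)
    pos_totals = pos_counts.sum(axis=1)
    neg_totals = neg_counts.sum(axis=1)
    results = []
    for position in FLANK_POSITIONS:
        n1, n2 = int(pos_totals[position]), int(neg_totals[position])
        if n1 == 0 or n2 == 0:
            continue
        for residue in AMINO_ACIDS:
            k1 = int(pos_counts.loc[position, residue])
            k2 = int(neg_counts.loc[position, residue])
            f1, f2 = k1 / n1, k2 / n2
            if f1 == f2:
                continue
            p = _two_proportion_p(k1, n1, k2, n2)
            if p < alpha:
                results.append(
                    EnrichmentResult(
                        position=position,
                        residue=residue,
                        direction="enriched" if f1 > f2 else "depleted",
                        p_value=p,
                        positive_freq=f1,
                        negative_freq=f2,
                    )
                )
    return results


def enrichment_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "position": r.position,
                "residue": r.residue,
                "direction": r.direction,
                "p_value": r.p_value,
                "positive_freq": r.positive_freq,
                "negative_freq": r.negative_freq,
            }
            for r in results
        ],
        columns=[
            "position",
            "residue",
            "direction",
            "p_value",
            "positive_freq",
            "negative_freq",
        ],
    )


def write_enrichment(results: Sequence[EnrichmentResult], path: str | Path) -> None:
    enrichment_frame(results).to_csv(path, sep="\t", index=False)


def write_composition(freq: pd.DataFrame, path: str | Path) -> None:
    freq.to_csv(path, sep="\t", index_label="position")
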