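"""Column conservation from multiple sequence alignments via Jensen-Shannon divergence.

Each alignment column's amino-acid distribution (pseudocounted) is
compared with a background distribution — by default the BLOSUM62
marginal frequencies — using the Jensen-Shannon divergence with equal
weights and base-2 logarithms, which bounds the score to [0, 1]; higher
means more conserved (further from background).  Columns dominated by
gaps carry no reliable signal and are reported missing.  A light window
smoothing mixes each column's score with the mean of its flanking
columns, rewarding conserved runs over isolated spikes.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from Bio import AlignIO
from scipy.stats import pearsonr, spearmanr

from .mtr_sequence import IntoleranceTrack

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP_CHARS = frozenset("-.")

#: BLOSUM62 marginal amino-acid frequencies (Henikoff & Henikoff),
#: the conventional background for alignment-based conservation.
BLOSUM62_BACKGROUND: dict[str, float] = {
    "A": 0.074, "C": 0.025, "D": 0.054, "E": 0.054, "F": 0.047,
    "G": 0.074, "H": 0.026, "I": 0.068, "K": 0.058, "L": 0.099,
    "M": 0.025, "N": 0.045, "P": 0.039, "Q": 0.034, "R": 0.052,
    "S": 0.057, "T": 0.051, "V": 0.073, "W": 0.013, "Y": 0.032,
}

DEFAULT_PSEUDOCOUNT = 1.0 / 50.0
DEFAULT_GAP_THRESHOLD = 0.30
DEFAULT_WINDOW = 3
DEFAULT_LAMBDA = 0.5


def background_vector(background: dict[str, float] | str | None = None) -> np.ndarray:
    """Background distribution as a normalised vector over the 20 amino acids."""
    if background is None or background == "blosum62":
        background = BLOSUM62_BACKGROUND
    elif background == "uniform":
        background = {aa: 1.0 for aa in AMINO_ACIDS}
    q = np.array([background[aa] for aa in AMINO_ACIDS], dtype=float)
    return q / q.sum()


@dataclass
class AlignmentColumn:
    letters: list[str]

    @property
    def gap_fraction(self) -> float:
        if not self.letters:
            return 1.0
        gaps = sum(1 for c in self.letters if c in GAP_CHARS)
        return gaps / len(self.letters)

    def distribution(self, pseudocount: float = DEFAULT_PSEUDOCOUNT) -> np.ndarray:
        counts = np.zeros(len(AMINO_ACIDS))
        for c in self.letters:
            c = c.upper()
            idx = AMINO_ACIDS.find(c)
            if idx >= 0:
                counts[idx] += 1
        total = counts.sum()
        if total == 0:
            raise ValueError("all-gap column has no distribution")
        counts += pseudocount
        return counts / counts.sum()


@dataclass
class ConservationTrack(IntoleranceTrack):
    gap_flags: np.ndarray | None = None


def _entropy(p: np.ndarray) -> float:
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum())


def column_jsd(
    column: AlignmentColumn | Sequence[str],
    background: dict[str, float] | str | np.ndarray | None = None,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> float:
    """Jensen-Shannon divergence between one column and the background.

    ``JSD(p, q) = H((p+q)/2) - [H(p) + H(q)] / 2`` with base-2 entropies,
    so the value lies in [0, 1]: 0 when the column matches the background
    exactly, approaching 1 for a perfectly conserved residue the
    background rarely uses.
    """
    if not isinstance(column, AlignmentColumn):
        column = AlignmentColumn(list(column))
    q = background if isinstance(background, np.ndarray) else background_vector(background)
    p = column.distribution(pseudocount)
    m = 0.5 * (p + q)
    return _entropy(m) - 0.5 * (_entropy(p) + _entropy(q))


def windowed_conservation(
    alignment,
    gene_id: str = "",
    window: int = DEFAULT_WINDOW,
    lam: float = DEFAULT_LAMBDA,
    gap_threshold: float = DEFAULT_GAP_THRESHOLD,
    background: dict[str, float] | str | None = None,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> ConservationTrack:
    """Per-column conservation with flank smoothing and gap masking.

    ``alignment`` is a sequence of equal-length aligned strings (or any
    Biopython alignment).  The smoothed score of column *i* is
    ``(1 - lam) * jsd_i + lam * mean(jsd over <= window flanking columns
    each side, excluding i)``.  Columns whose gap fraction exceeds
    ``gap_threshold`` are missing, flagged in ``gap_flags``, and do not
    contribute to their neighbours' smoothing.
    """
    seqs = [str(getattr(rec, "seq", rec)) for rec in alignment]
    if not seqs:
        raise ValueError("empty alignment")
    length = len(seqs[0])
    if any(len(s) != length for s in seqs):
        raise ValueError("alignment rows have unequal lengths")
    if window >= length:
        raise ValueError("window must be smaller than the alignment length")

    qvec = background_vector(background)
    raw = np.full(length, np.nan)
    gap_flags = np.zeros(length, dtype=bool)
    for i in range(length):
        col = AlignmentColumn([s[i] for s in seqs])
        if col.gap_fraction > gap_threshold:
            gap_flags[i] = True
            continue
        raw[i] = column_jsd(col, qvec, pseudocount)

    values = np.full(length, np.nan)
    for i in range(length):
        if np.isnan(raw[i]):
            continue
        lo, hi = max(0, i - window), min(length, i + window + 1)
        flank = np.concatenate([raw[lo:i], raw[i + 1 : hi]])
        flank = flank[~np.isnan(flank)]
        if flank.size and lam > 0:
            values[i] = (1.0 - lam) * raw[i] + lam * float(flank.mean())
        else:
            values[i] = raw[i]
    return ConservationTrack(
        gene_id=gene_id, score_name="conservation", values=values, gap_flags=gap_flags
    )


def read_msa_fasta(path: str | Path):
    """Read an aligned FASTA file (equal-length records)."""
    return AlignIO.read(str(path), "fasta")


def correlate_tracks(
    a: IntoleranceTrack | np.ndarray,
    b: IntoleranceTrack | np.ndarray,
    method: str = "pearson",
) -> dict:
    """Correlation between two per-position tracks over jointly non-missing positions.

    Returns ``{"r": ., "p": ., "n": ., "undefined": bool}``; a
    zero-variance input yields an undefined correlation (flagged) rather
    than an exception.
    """
    x = a.values if isinstance(a, IntoleranceTrack) else np.asarray(a, dtype=float)
    y = b.values if isinstance(b, IntoleranceTrack) else np.asarray(b, dtype=float)
    if len(x) != len(y):
        raise ValueError("tracks have different lengths")
    mask = ~(np.isnan(x) | np.isnan(y))
    n = int(mask.sum())
    if n < 3:
        raise ValueError(f"only {n} jointly non-missing positions (need >= 3)")
    xv, yv = x[mask], y[mask]
    if np.ptp(xv) == 0 or np.ptp(yv) == 0:
        return {"r": float("nan"), "p": float("nan"), "n": n, "undefined": True}
    if method == "pearson":
        r, p = pearsonr(xv, yv)
    elif method == "spearman":
        r, p = spearmanr(xv, yv)
    else:
        raise ValueError(f"unknown method {method!r}")
    return {"r": float(r), "p": float(p), "n": n, "undefined": False}
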