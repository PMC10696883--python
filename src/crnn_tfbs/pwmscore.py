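"""Log-odds PWM scoring (FIMO-style), the classical comparator.

Counts become log2-odds against a background model with a pseudocount:

    weight[b, i] = log2( (counts[b, i] + pc * bg[b]) / (colsum_i + pc) / bg[b] )

Scores are in bits; a negative best score means the sequence looks more like
background than motif, which is the "PWM non-binding" arm of the
non-canonical discovery filter.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from crnn_tfbs.errors import DegenerateDataError, InputError, ValidationError
from crnn_tfbs.seqio import ALPHABET, BASES, PositionFrequencyMatrix, reverse_complement

UNIFORM_BACKGROUND = np.full(4, 0.25)

#: sentinel for windows containing N (unmatchable)
NEG_INF = float("-inf")

_BASE_INDEX = {b: i for i, b in enumerate(BASES)}


@dataclass(frozen=True)
class LogOddsMatrix:
    """4 x w log2-odds weights (bits), rows A,C,G,T."""

    weights: np.ndarray
    background: np.ndarray
    pseudocount: float
    motif_id: str = ""

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=np.float64)
        bg = np.asarray(self.background, dtype=np.float64)
        if w.ndim != 2 or w.shape[0] != 4:
            raise ValidationError(f"weights must be 4 x w, got {w.shape}")
        if bg.shape != (4,) or abs(bg.sum() - 1.0) > 1e-9:
            raise ValidationError("background must be a 4-vector summing to 1")
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "background", bg)

    @property
    def width(self) -> int:
        return int(self.weights.shape[1])

    @property
    def max_score(self) -> float:
        """Best attainable score (per-column maxima summed)."""
        return float(self.weights.max(axis=0).sum())


@dataclass(frozen=True)
class PwmHit:
    """Best PWM window on a scanned sequence."""

    score: float
    offset: int
    strand: str
    window_seq: str


def pfm_to_log_odds(
    pfm: PositionFrequencyMatrix,
    background: np.ndarray | Sequence[float] = UNIFORM_BACKGROUND,
    pseudocount: float = 0.1,
) -> LogOddsMatrix:
    """Convert a count matrix to log2-odds weights against a background."""
    bg = np.asarray(background, dtype=np.float64)
    if (bg <= 0).any() or abs(bg.sum() - 1.0) > 1e-9:
        raise InputError("background must be strictly positive and sum to 1")
    if pseudocount < 0:
        raise InputError("pseudocount must be >= 0")
    colsums = pfm.counts.sum(axis=0)
    if pseudocount == 0 and (pfm.counts == 0).any():
        raise DegenerateDataError(
            "zero counts with pseudocount 0 give -inf weights; use pseudocount > 0"
        )
    probs = (pfm.counts + pseudocount * bg[:, None]) / (colsums + pseudocount)[None, :]
    weights = np.log2(probs / bg[:, None])
    return LogOddsMatrix(
        weights=weights, background=bg, pseudocount=pseudocount, motif_id=pfm.motif_id
    )


def score_window(lom: LogOddsMatrix, window: str) -> float:
    """Sum of per-position weights for one window of length w.

    A window containing N scores -inf (unmatchable) rather than raising.
    """
    window = window.upper()
    if len(window) != lom.width:
        raise InputError(
            f"window length {len(window)} != matrix width {lom.width}"
        )
    if "N" in window:
        return NEG_INF
    try:
        rows = [_BASE_INDEX[c] for c in window]
    except KeyError as exc:
        raise InputError(f"invalid character {exc} in window {window!r}") from exc
    return float(lom.weights[rows, np.arange(lom.width)].sum())


def _all_window_scores(lom: LogOddsMatrix, seq: str) -> np.ndarray:
    """Forward-strand score of every window (vectorized); N windows -> -inf."""
    codes = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    row = np.full(256, -1, dtype=np.int64)
    for i, b in enumerate(BASES):
        row[ord(b)] = i
    idx = row[codes]
    w = lom.width
    windows = np.lib.stride_tricks.sliding_window_view(idx, w)
    valid = (windows >= 0).all(axis=1)
    scores = np.full(windows.shape[0], NEG_INF)
    if valid.any():
        safe = np.where(windows[valid] >= 0, windows[valid], 0)
        scores[valid] = lom.weights[safe, np.arange(w)].sum(axis=1)
    return scores


def best_hit(lom: LogOddsMatrix, seq: str, both_strands: bool = True) -> PwmHit:
    """Maximal-scoring window over all offsets (and both strands if flagged).

    Ties break toward the smallest offset, then the + strand. The offset of a
    minus-strand hit refers to the forward-strand coordinate of the window;
    ``window_seq`` is the minus-strand (reverse-complemented) sequence read
    at that offset.
    """
    seq = seq.upper()
    bad = set(seq) - set(ALPHABET)
    if bad:
        raise InputError(f"invalid characters in sequence: {sorted(bad)!r}")
    w = lom.width
    if len(seq) < w:
        raise InputError(f"sequence length {len(seq)} < matrix width {w}")
    fwd_scores = _all_window_scores(lom, seq)
    if both_strands:
        # minus-strand window at forward offset o is the revcomp of
        # seq[o:o+w]; scoring it equals scanning revcomp(seq) at the
        # mirrored offset
        rc_scores = _all_window_scores(lom, reverse_complement(seq))[::-1]
        stacked = np.stack([fwd_scores, rc_scores])  # row 0: +, row 1: -
        flat_best = int(np.argmax(stacked.T))  # offset-major: smallest offset, + first
        offset, strand_idx = divmod(flat_best, 2)
        strand = "+-"[strand_idx]
        score = float(stacked[strand_idx, offset])
    else:
        offset = int(np.argmax(fwd_scores))
        strand = "+"
        score = float(fwd_scores[offset])
    window = seq[offset : offset + w]
    if strand == "-":
        window = reverse_complement(window)
    return PwmHit(score=score, offset=offset, strand=strand, window_seq=window)


def scan_records(lom, records, both_strands: bool = True) -> list[tuple[str, PwmHit]]:
    """Best hit per record; convenience for TSV export and CLI."""
    return [(rec.id, best_hit(lom, rec.seq, both_strands)) for rec in records]
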