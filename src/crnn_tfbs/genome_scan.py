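"""Peak preparation, sliding-window scoring, non-canonical site discovery,
and in-silico saturation mutagenesis.

A "scorer" here is any callable mapping a list of fixed-width windows to a
numeric score per window — the neural classifier's ``score_windows`` or a
PWM closure — so the same scan machinery serves both arms of the discovery
filter (neural score > 0.99 while PWM log-odds < 0).
"""

from __future__ import annotations

import bisect
import logging
from dataclasses import dataclass, replace
from typing import Callable, Sequence

import numpy as np
from scipy import stats

from crnn_tfbs.errors import AlignmentError, InputError
from crnn_tfbs.seqio import BASES, PeakRecord, SequenceRecord

logger = logging.getLogger(__name__)

Scorer = Callable[[Sequence[str]], "np.ndarray"]


@dataclass(frozen=True)
class ScanResult:
    """Best window of one peak under one scorer."""

    peak_id: str
    best_offset: int
    best_window: str
    score: float
    percentile: float | None = None
    chip_score: float | None = None


@dataclass(frozen=True)
class VariantEffect:
    """Effect of a single-nucleotide substitution on the predicted score.

    ``position`` is 1-based within the parent window, matching the
    convention of human-readable variant reports.
    """

    parent_id: str
    position: int
    ref_base: str
    alt_base: str
    variant_seq: str
    score: float
    delta: float


def filter_peaks(peaks: Sequence[PeakRecord], q_threshold: float) -> list[PeakRecord]:
    """Retain peaks with linear q-value strictly below ``q_threshold``.

    The threshold is expressed as a linear q (e.g. 1e-5) and converted to
    the stored -log10 dialect, preventing silent threshold inversion:
    q < t  ⇔  -log10(q) > -log10(t).
    """
    if not (0 < q_threshold <= 1):
        raise InputError(f"q_threshold must be in (0, 1], got {q_threshold}")
    neglog_t = -np.log10(q_threshold)
    kept = [
        p for p in peaks
        if (p.qvalue > neglog_t if p.qvalue_is_neglog10 else p.qvalue < q_threshold)
    ]
    if not kept:
        logger.warning("q-value filter at %g removed all %d peaks", q_threshold, len(peaks))
    return kept


def remove_overlapping(
    negatives: Sequence[PeakRecord], positives: Sequence[PeakRecord]
) -> tuple[list[PeakRecord], int]:
    """Drop negatives sharing >= 1 bp with any positive on the same chromosome.

    Half-open overlap test (a.start < b.end and b.start < a.end); abutting
    intervals share no base and are kept. Returns survivors in input order
    plus the number removed.
    """
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for p in positives:
        by_chrom.setdefault(p.chrom, []).append((p.start, p.end))
    for ivs in by_chrom.values():
        ivs.sort()
    survivors = []
    removed = 0
    for n in negatives:
        ivs = by_chrom.get(n.chrom, [])
        starts = [iv[0] for iv in ivs]
        # candidate positives with start < n.end
        hi = bisect.bisect_left(starts, n.end)
        overlap = any(ivs[i][1] > n.start for i in range(hi))
        if overlap:
            removed += 1
        else:
            survivors.append(n)
    return survivors, removed


def scan_sequence(
    scorer: Scorer,
    seq: SequenceRecord,
    window: int,
    stride: int = 1,
    chip_score: float | None = None,
) -> ScanResult:
    """Highest-scoring fixed-width window of a sequence.

    All ``floor((L - window) / stride) + 1`` windows are evaluated in one
    scorer call; ties break toward the smallest offset.
    """
    L = seq.length
    if L < window:
        raise InputError(f"sequence {seq.id!r} length {L} < window {window}")
    offsets = list(range(0, L - window + 1, stride))
    windows = [seq.seq[o : o + window] for o in offsets]
    scores = np.asarray(scorer(windows), dtype=float)
    best = int(np.argmax(scores))  # argmax returns the first maximum: smallest offset
    return ScanResult(
        peak_id=seq.id,
        best_offset=offsets[best],
        best_window=windows[best],
        score=float(scores[best]),
        chip_score=chip_score,
    )


def scan_all(
    scorer: Scorer,
    seqs: Sequence[SequenceRecord],
    window: int,
    stride: int = 1,
    chip_scores: Sequence[float] | None = None,
) -> list[ScanResult]:
    """Scan a collection, silently dropping sequences shorter than the window
    (with a logged count), then attach within-collection percentiles."""
    results = []
    dropped = 0
    for i, s in enumerate(seqs):
        if s.length < window:
            dropped += 1
            continue
        cs = chip_scores[i] if chip_scores is not None else None
        results.append(scan_sequence(scorer, s, window, stride, chip_score=cs))
    if dropped:
        logger.warning("%d sequences shorter than window %d dropped", dropped, window)
    return assign_percentiles(results)


def assign_percentiles(results: Sequence[ScanResult]) -> list[ScanResult]:
    """Percentile = 100 * mean rank / N within the given result set.

    The maximum score maps to 100; ties share their mean rank, so the
    percentile is monotone in score.
    """
    if not results:
        raise InputError("need at least one result")
    scores = np.array([r.score for r in results], dtype=float)
    ranks = stats.rankdata(scores)  # midranks, 1-based
    pct = 100.0 * ranks / len(results)
    return [replace(r, percentile=float(p)) for r, p in zip(results, pct)]


@dataclass(frozen=True)
class NoncanonicalHit:
    peak_id: str
    rnn_score: float
    rnn_window: str
    pwm_score: float
    pwm_window: str


def discover_noncanonical(
    rnn_results: Sequence[ScanResult],
    pwm_results: Sequence[ScanResult],
    rnn_min: float = 0.99,
    pwm_max: float = 0.0,
) -> list[NoncanonicalHit]:
    """Peaks scored binding by the neural model but non-binding by the PWM.

    Selection uses strict inequalities (neural score > ``rnn_min`` and PWM
    log-odds < ``pwm_max``); output is sorted by descending neural score.
    Both result lists must cover exactly the same peak ids.
    """
    rnn_by_id = {r.peak_id: r for r in rnn_results}
    pwm_by_id = {r.peak_id: r for r in pwm_results}
    if set(rnn_by_id) != set(pwm_by_id):
        only_rnn = set(rnn_by_id) - set(pwm_by_id)
        only_pwm = set(pwm_by_id) - set(rnn_by_id)
        raise AlignmentError(
            f"result sets differ: {len(only_rnn)} ids only in neural results, "
            f"{len(only_pwm)} only in PWM results"
        )
    hits = [
        NoncanonicalHit(
            peak_id=pid,
            rnn_score=r.score,
            rnn_window=r.best_window,
            pwm_score=pwm_by_id[pid].score,
            pwm_window=pwm_by_id[pid].best_window,
        )
        for pid, r in rnn_by_id.items()
        if r.score > rnn_min and pwm_by_id[pid].score < pwm_max
    ]
    hits.sort(key=lambda h: (-h.rnn_score, h.peak_id))
    return hits


def apply_variant(parent: str, position: int, alt_base: str) -> str:
    """Substitute ``alt_base`` at 1-based ``position`` of ``parent``."""
    if not (1 <= position <= len(parent)):
        raise InputError(f"position {position} outside 1..{len(parent)}")
    idx = position - 1
    return parent[:idx] + alt_base + parent[idx + 1 :]


def saturation_mutagenesis(seq: SequenceRecord, scorer: Scorer) -> list[VariantEffect]:
    """Score every possible single-base substitution of ``seq``.

    Emits exactly 3*L variants (all bases except the reference at each
    position), each scored in one batch; deltas are relative to the parent
    score. Positions are reported 1-based.
    """
    if "N" in seq.seq:
        raise InputError(f"{seq.id!r}: N-containing sequences cannot be mutagenized")
    parent = seq.seq
    variants: list[tuple[int, str, str, str]] = []
    for pos0, ref in enumerate(parent):
        for alt in BASES:
            if alt == ref:
                continue
            variants.append(
                (pos0 + 1, ref, alt, apply_variant(parent, pos0 + 1, alt))
            )
    scores = np.asarray(scorer([parent] + [v[3] for v in variants]), dtype=float)
    parent_score = float(scores[0])
    return [
        VariantEffect(
            parent_id=seq.id,
            position=pos,
            ref_base=ref,
            alt_base=alt,
            variant_seq=vs,
            score=float(s),
            delta=float(s) - parent_score,
        )
        for (pos, ref, alt, vs), s in zip(variants, scores[1:])
    ]


def select_top_variants(
    effects: Sequence[VariantEffect], k: int
) -> list[VariantEffect]:
    """The ``k`` variants with the largest absolute score change.

    Ties break by position, then alphabetically by alternate base.
    """
    if k > len(effects):
        raise InputError(f"k={k} exceeds {len(effects)} effects")
    ranked = sorted(effects, key=lambda e: (-abs(e.delta), e.position, e.alt_base))
    return ranked[:k]
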