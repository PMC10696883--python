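"""Sequence and interval IO: FASTA, JASPAR PFM, narrowPeak, encodings.

All coordinates are 0-based half-open (BED convention) internally; 1-based
positions appear only in human-readable variant reports.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO, motifs
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from crnn_tfbs.errors import (
    AlphabetError,
    LookupFailure,
    ParseError,
    PatternError,
    ValidationError,
)

logger = logging.getLogger(__name__)

ALPHABET = "ACGTN"
BASES = "ACGT"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: IUPAC ambiguity codes -> the set of concrete bases each matches.
IUPAC_CODES: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGTN"),
}

# one-hot lookup: row per byte value, A,C,G,T columns; N -> all-zero row
_ONEHOT_LUT = np.zeros((256, 4), dtype=np.float64)
for _i, _b in enumerate(BASES):
    _ONEHOT_LUT[ord(_b), _i] = 1.0


def _check_alphabet(seq: str, where: str = "sequence") -> None:
    bad = set(seq) - set(ALPHABET)
    if bad:
        raise AlphabetError(
            f"{where} contains characters outside {{A,C,G,T,N}}: {sorted(bad)!r}"
        )


@dataclass(frozen=True)
class SequenceRecord:
    """An identified DNA string over {A,C,G,T,N}, stored uppercase."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "seq", self.seq.upper())
        _check_alphabet(self.seq, f"record {self.id!r}")

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class PositionFrequencyMatrix:
    """Per-position base counts, rows in A,C,G,T order, shape (4, width)."""

    counts: np.ndarray
    motif_id: str = ""

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.float64)
        if counts.ndim != 2 or counts.shape[0] != 4:
            raise ValidationError(f"counts must be 4 x w, got shape {counts.shape}")
        if counts.shape[1] < 1:
            raise ValidationError("PFM width must be >= 1")
        if (counts < 0).any():
            raise ValidationError("PFM counts must be non-negative")
        if (counts.sum(axis=0) <= 0).any():
            raise ValidationError("every PFM column needs at least one positive count")
        object.__setattr__(self, "counts", counts)

    @property
    def width(self) -> int:
        return int(self.counts.shape[1])

    @property
    def consensus(self) -> str:
        """Highest-count base per column (ties broken in A,C,G,T order)."""
        return "".join(BASES[i] for i in self.counts.argmax(axis=0))


@dataclass
class PeakRecord:
    """A ChIP-Seq peak interval with enrichment score, q-value and summit.

    ``qvalue`` is stored as -log10(q) (the narrowPeak dialect); the
    ``qvalue_is_neglog10`` flag records the dialect explicitly so thresholds
    expressed as linear q can be converted without silent inversion.
    """

    chrom: str
    start: int
    end: int
    name: str = "."
    chip_score: float = 0.0
    qvalue: float = 0.0
    summit_offset: int = 0
    qvalue_is_neglog10: bool = True
    seq: str | None = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValidationError(
                f"peak {self.name}: start {self.start} >= end {self.end}"
            )
        if not (0 <= self.summit_offset < self.end - self.start):
            raise ValidationError(
                f"peak {self.name}: summit offset {self.summit_offset} outside "
                f"[0, {self.end - self.start})"
            )
        if self.qvalue_is_neglog10 and self.qvalue < 0:
            raise ValidationError(f"peak {self.name}: -log10 q-value must be >= 0")

    @property
    def summit(self) -> int:
        """Absolute 0-based summit position."""
        return self.start + self.summit_offset

    @property
    def qvalue_linear(self) -> float:
        return 10.0 ** (-self.qvalue) if self.qvalue_is_neglog10 else self.qvalue


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path) -> list[SequenceRecord]:
    """Read a FASTA file into :class:`SequenceRecord` objects.

    Sequences are uppercased; record order is preserved. Raises
    :class:`ParseError` on a malformed header (naming the line) and
    :class:`AlphabetError` on characters outside {A,C,G,T,N}.
    """
    # pre-scan for a body line appearing before any header, with line numbers
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if not stripped.startswith(">"):
                raise ParseError(
                    f"{path}: line {lineno}: expected FASTA header line "
                    f"starting with '>', got {stripped[:30]!r}"
                )
            break
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    with open(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            try:
                record = SequenceRecord(id=rec.id, seq=str(rec.seq))
            except AlphabetError as exc:
                raise AlphabetError(f"{path}: {exc}") from exc
            if record.id in seen:
                raise ParseError(f"{path}: duplicate record id {record.id!r}")
            seen.add(record.id)
            records.append(record)
    return records


def write_fasta(records: Iterable[SequenceRecord], path) -> None:
    """Write records to FASTA (one line per sequence)."""
    bio = [SeqRecord(Seq(r.seq), id=r.id, description="") for r in records]
    with open(path, "w") as fh:
        SeqIO.write(bio, fh, "fasta-2line")


# ---------------------------------------------------------------------------
# Elementary sequence operations


def reverse_complement(seq: str) -> str:
    """Watson-Crick complement, reversed; N maps to N. An involution."""
    seq = seq.upper()
    _check_alphabet(seq)
    return seq.translate(_COMPLEMENT)[::-1]


def one_hot_encode(seq: str) -> np.ndarray:
    """Encode a DNA string as an L x 4 matrix (columns A,C,G,T).

    N encodes as an all-zero row, so a trained model can learn to ignore
    unknown bases and row sums stay testable (exactly 1 for A/C/G/T rows).
    """
    seq = seq.upper()
    _check_alphabet(seq)
    if not seq:
        return np.zeros((0, 4), dtype=np.float64)
    codes = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _ONEHOT_LUT[codes].copy()


def one_hot_decode(matrix: np.ndarray) -> str:
    """Inverse of :func:`one_hot_encode`; all-zero rows decode to N."""
    matrix = np.asarray(matrix)
    if matrix.ndim != 2 or matrix.shape[1] != 4:
        raise ValidationError(f"expected an L x 4 matrix, got shape {matrix.shape}")
    out = []
    for row in matrix:
        if row.sum() == 0:
            out.append("N")
        else:
            out.append(BASES[int(row.argmax())])
    return "".join(out)


def _expand_pattern(pattern: str) -> list[frozenset[str]]:
    sets = []
    for ch in pattern.upper():
        if ch not in IUPAC_CODES:
            raise PatternError(f"invalid IUPAC code {ch!r} in pattern {pattern!r}")
        sets.append(IUPAC_CODES[ch])
    return sets


def iupac_contains(seq: str, pattern: str, both_strands: bool = False) -> bool:
    """True iff some window of ``seq`` matches the IUPAC ``pattern``.

    With ``both_strands`` the reverse complement of ``seq`` is searched too.
    A concrete N in ``seq`` is matched only by pattern code N.
    """
    seq = seq.upper()
    _check_alphabet(seq)
    sets = _expand_pattern(pattern)
    w = len(sets)
    if w == 0:
        return True
    strands = [seq, reverse_complement(seq)] if both_strands else [seq]
    for s in strands:
        for off in range(len(s) - w + 1):
            if all(s[off + j] in sets[j] for j in range(w)):
                return True
    return False


# ---------------------------------------------------------------------------
# JASPAR PFM


def read_jaspar_pfm(path) -> PositionFrequencyMatrix:
    """Read the first motif of a JASPAR-format PFM file.

    Rows may appear in any order; the returned counts are always in
    A,C,G,T row order. Ragged or missing base rows raise :class:`ParseError`.
    """
    with open(path) as fh:
        try:
            parsed = motifs.parse(fh, "jaspar")
            motif_list = list(parsed)
        except Exception as exc:  # biopython raises bare Exception on ragged rows
            raise ParseError(f"{path}: not a valid JASPAR PFM file: {exc}") from exc
    if not motif_list:
        raise ParseError(f"{path}: no motifs found")
    m = motif_list[0]
    try:
        counts = np.array([m.counts[b] for b in BASES], dtype=np.float64)
    except KeyError as exc:
        raise ParseError(f"{path}: missing base row {exc}") from exc
    motif_id = m.matrix_id if getattr(m, "matrix_id", None) else (m.name or "")
    return PositionFrequencyMatrix(counts=counts, motif_id=str(motif_id))


def write_jaspar_pfm(pfm: PositionFrequencyMatrix, path) -> None:
    """Write a PFM in JASPAR text format (bracketed count rows)."""
    with open(path, "w") as fh:
        fh.write(f">{pfm.motif_id or 'motif'} {pfm.motif_id or 'motif'}\n")
        for i, b in enumerate(BASES):
            row = " ".join(f"{v:.0f}" if float(v).is_integer() else f"{v:g}"
                           for v in pfm.counts[i])
            fh.write(f"{b}  [ {row} ]\n")


# ---------------------------------------------------------------------------
# narrowPeak / BED


def read_narrowpeak(path) -> list[PeakRecord]:
    """Read ENCODE narrowPeak (BED6+4) into :class:`PeakRecord` objects.

    Column 7 (signalValue) becomes ``chip_score``; column 9 is -log10(q);
    column 10 is the summit offset (value -1 falls back to the interval
    midpoint with a logged warning). Plain BED4 is accepted, with the summit
    defaulting to the midpoint and score/q-value set to 0.
    """
    peaks: list[PeakRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) == 1:
                fields = line.split()
            if len(fields) not in (4, 10):
                raise ParseError(
                    f"{path}: line {lineno}: expected 10 (narrowPeak) or 4 "
                    f"(BED4) columns, got {len(fields)}"
                )
            chrom, name = fields[0], fields[3]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(
                    f"{path}: line {lineno}: non-integer coordinates"
                ) from exc
            if len(fields) == 10:
                chip_score = float(fields[6])
                qvalue = float(fields[8])
                summit = int(fields[9])
            else:
                chip_score, qvalue, summit = 0.0, 0.0, -1
            if summit == -1:
                summit = (end - start) // 2
                logger.warning(
                    "%s line %d: peak %s has no summit; using interval midpoint",
                    path, lineno, name,
                )
            try:
                peaks.append(
                    PeakRecord(
                        chrom=chrom, start=start, end=end, name=name,
                        chip_score=chip_score, qvalue=qvalue, summit_offset=summit,
                    )
                )
            except ValidationError as exc:
                raise ValidationError(f"{path}: line {lineno}: {exc}") from exc
    return peaks


def write_narrowpeak(peaks: Sequence[PeakRecord], path) -> None:
    with open(path, "w") as fh:
        for p in peaks:
            fh.write(
                "\t".join(
                    [
                        p.chrom, str(p.start), str(p.end), p.name, "0", ".",
                        f"{p.chip_score:g}", "-1", f"{p.qvalue:g}",
                        str(p.summit_offset),
                    ]
                )
                + "\n"
            )


def extract_summit_window(
    peak: PeakRecord,
    source: Mapping[str, str],
    flank: int = 50,
) -> SequenceRecord | None:
    """Extract the ``[summit - flank, summit + flank)`` sequence of a peak.

    ``source`` maps contig name to sequence (a plain dict or any mapping
    view of a genome FASTA, e.g. ``pyfaidx.Fasta`` works after ``str()``).
    Windows overrunning the contig are dropped (returns None) with a logged
    warning rather than clipped: downstream scorers need fixed-length input
    and clipped windows would bias scores.
    """
    if peak.chrom not in source:
        raise LookupFailure(f"contig {peak.chrom!r} absent from sequence source")
    contig = str(source[peak.chrom])
    lo, hi = peak.summit - flank, peak.summit + flank
    if lo < 0 or hi > len(contig):
        logger.warning(
            "peak %s: window [%d,%d) overruns contig %s (length %d); dropped",
            peak.name, lo, hi, peak.chrom, len(contig),
        )
        return None
    return SequenceRecord(id=peak.name, seq=contig[lo:hi].upper())
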