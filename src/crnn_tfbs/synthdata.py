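"""Synthetic inputs with the statistical structure the pipeline assumes.

Three generators cover the three experimental data kinds the pipeline
consumes, at desk scale and bit-reproducible from a seed:

* ``simulate_reads`` — fixed-length selection reads: i.i.d. background at a
  chosen GC content, with a motif instance planted in a configurable
  fraction of reads. A small fraction of planted reads carries a second,
  "non-canonical" motif that the canonical PWM scores below background —
  emulating a selection library containing two binding modes, only one of
  which the PWM knows about.
* ``simulate_peaks`` — 100-nt peak windows with a summit-proximal site
  whose fidelity and ChIP score decay with peak rank, plus a matched decoy
  set built by dinucleotide-shuffling each positive window (no planted
  site, identical dinucleotide composition).
* ``simulate_kd`` — dissociation constants monotonically decreasing with
  true site strength, censored above a detection threshold.

Every generator also emits a ground-truth table; tests read the truth
rather than re-deriving it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from crnn_tfbs.errors import AlphabetError, ConfigError
from crnn_tfbs.negatives import dinucleotide_shuffle
from crnn_tfbs.seqio import (
    BASES,
    PeakRecord,
    PositionFrequencyMatrix,
    SequenceRecord,
    iupac_contains,
)

#: IUPAC core pattern the canonical motif carries and the non-canonical
#: motif must avoid (on both strands) for the discovery experiment to be
#: meaningful by construction.
CORE_PATTERN = "CNNG"


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator settings; the defaults are the package's study conditions.

    ``kd_min``/``kd_slope``/``detection_threshold`` give sub-µM constants
    for full-strength sites and censoring ("no binding detected") below
    site strength 0.25, mirroring the structure of a calorimetry panel with
    a 9 µM detection limit.
    """

    n_reads: int = 7200
    read_length: int = 20
    planted_fraction: float = 1.0
    canonical_consensus: str = "AAACCGGTTT"
    motif_softness: float = 0.05
    gc_content: float = 0.5
    noncanonical_consensus: str = "TTTTCCACTTTG"
    noncanonical_fraction: float = 0.1
    n_peaks: int = 500
    peak_length: int = 100
    signal_decay: float = 1.0
    chip_score_noise_sd: float = 0.1
    kd_min: float = 0.1
    kd_slope: float = 6.0
    kd_noise_sd: float = 0.0
    detection_threshold: float = 9.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("planted_fraction", "noncanonical_fraction", "gc_content"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if not (0.0 <= self.motif_softness < 0.75):
            raise ConfigError("motif_softness must be in [0, 0.75)")
        if self.detection_threshold <= 0:
            raise ConfigError("detection_threshold must be > 0")
        for cons in (self.canonical_consensus, self.noncanonical_consensus):
            if set(cons) - set(BASES):
                raise AlphabetError(f"consensus {cons!r} not over A,C,G,T")
        if iupac_contains(self.noncanonical_consensus, CORE_PATTERN, both_strands=True):
            raise ConfigError(
                f"noncanonical consensus {self.noncanonical_consensus!r} contains "
                f"the {CORE_PATTERN} core on some strand"
            )
        if self.read_length < len(self.canonical_consensus):
            raise ConfigError("read_length shorter than the canonical motif")
        if self.peak_length < len(self.canonical_consensus) + 20:
            raise ConfigError("peak_length must exceed motif width + 20")


@dataclass(frozen=True)
class TruthRow:
    id: str
    has_motif: bool
    motif_kind: str  # canonical | noncanonical | none
    motif_offset: int | None
    true_strength: float


def pwm_from_consensus(
    consensus: str, softness: float, motif_id: str = "synthetic"
) -> PositionFrequencyMatrix:
    """A PFM putting weight 1 - softness on the consensus base per column.

    The remaining softness splits equally over the other three bases;
    counts are scaled to 100 per column.
    """
    if set(consensus.upper()) - set(BASES):
        raise AlphabetError(f"consensus {consensus!r} not over A,C,G,T")
    if not (0.0 <= softness < 0.75):
        raise ConfigError("softness must be in [0, 0.75)")
    counts = np.full((4, len(consensus)), 100.0 * softness / 3.0)
    for i, b in enumerate(consensus.upper()):
        counts[BASES.index(b), i] = 100.0 * (1.0 - softness)
    return PositionFrequencyMatrix(counts=counts, motif_id=motif_id)


def _background_probs(gc: float) -> np.ndarray:
    return np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    """Background bases as indices into A,C,G,T."""
    return rng.choice(4, size=length, p=_background_probs(gc))


def _sample_instance(
    rng: np.random.Generator, consensus: str, mismatch_prob: float
) -> str:
    """A motif instance: per position, consensus base with prob 1 - mismatch,
    else one of the other three bases uniformly."""
    out = []
    for b in consensus:
        if rng.random() < mismatch_prob:
            others = [x for x in BASES if x != b]
            out.append(others[rng.integers(3)])
        else:
            out.append(b)
    return "".join(out)


def simulate_reads(
    cfg: SyntheticConfig,
) -> tuple[list[SequenceRecord], list[TruthRow]]:
    """Fixed-length reads with planted motif instances plus a truth table.

    ``planted_fraction`` of reads receive a motif at a uniform random valid
    offset; of those, ``noncanonical_fraction`` (exact count) carry the
    non-canonical consensus instead of the canonical one. A read's
    ``true_strength`` is its instance's realized per-position identity to
    the consensus (1.0 for background-free exact instances, 0 for
    unplanted reads).
    """
    if cfg.n_reads < 1:
        raise ConfigError("n_reads must be >= 1")
    rng = np.random.default_rng(cfg.seed)
    n_planted = int(round(cfg.planted_fraction * cfg.n_reads))
    planted_idx = set(rng.choice(cfg.n_reads, size=n_planted, replace=False).tolist())
    n_noncanon = int(round(cfg.noncanonical_fraction * n_planted))
    noncanon_idx = set(
        rng.choice(sorted(planted_idx), size=n_noncanon, replace=False).tolist()
    )
    width = len(str(cfg.n_reads))
    records, truth = [], []
    for i in range(cfg.n_reads):
        idx = _random_seq(rng, cfg.read_length, cfg.gc_content)
        seq = "".join(BASES[j] for j in idx)
        if i in planted_idx:
            kind = "noncanonical" if i in noncanon_idx else "canonical"
            consensus = (
                cfg.noncanonical_consensus
                if kind == "noncanonical"
                else cfg.canonical_consensus
            )
            instance = _sample_instance(rng, consensus, cfg.motif_softness)
            offset = int(rng.integers(cfg.read_length - len(consensus) + 1))
            seq = seq[:offset] + instance + seq[offset + len(consensus) :]
            strength = sum(a == b for a, b in zip(instance, consensus)) / len(consensus)
            truth.append(TruthRow(f"read_{i:0{width}d}", True, kind, offset, strength))
        else:
            truth.append(TruthRow(f"read_{i:0{width}d}", False, "none", None, 0.0))
        records.append(SequenceRecord(id=f"read_{i:0{width}d}", seq=seq))
    return records, truth


def _plant_region_core_free(
    rng: np.random.Generator,
    peak: list[str],
    instance: str,
    start: int,
    flank: int,
    gc: float,
    max_tries: int = 200,
) -> None:
    """Write ``instance`` into ``peak`` at ``start`` and resample the
    ``flank`` bases on each side until the whole stretch is CNNG-free on
    both strands (so every scan window covering the instance is too)."""
    w = len(instance)
    lo = max(0, start - flank)
    hi = min(len(peak), start + w + flank)
    peak[start : start + w] = list(instance)
    for _ in range(max_tries):
        stretch = "".join(peak[lo:hi])
        if not iupac_contains(stretch, CORE_PATTERN, both_strands=True):
            return
        for j in list(range(lo, start)) + list(range(start + w, hi)):
            peak[j] = BASES[int(rng.choice(4, p=_background_probs(gc)))]
    raise RuntimeError("could not build a core-free non-canonical region")


def simulate_peaks(
    cfg: SyntheticConfig,
) -> tuple[list[PeakRecord], list[PeakRecord], list[TruthRow]]:
    """Peak windows with rank-decaying site strength, plus matched decoys.

    Peak ``i`` (rank order) has generative strength
    ``s_i = exp(-signal_decay * i / (n_peaks - 1))``; its motif instance is
    sampled at mismatch probability ``motif_softness + 0.25 * (1 - s_i)``
    and placed with its center within ±10 nt of the summit. The ChIP score
    is ``10 * s_i`` with multiplicative lognormal noise and the -log10
    q-value is the deterministic function ``5 + chip_score`` (so every
    positive passes a linear q < 1e-5 filter by construction). An exact
    count ``round(noncanonical_fraction * n_peaks)`` of peaks carries the
    non-canonical consensus; its neighbourhood is regenerated until free of
    the CNNG core on both strands. Decoys are dinucleotide shuffles of each
    positive window (same composition, no site) on a separate contig.
    """
    if cfg.n_peaks < 1:
        raise ConfigError("n_peaks must be >= 1")
    from crnn_tfbs.pwmscore import best_hit, pfm_to_log_odds

    canonical_lom = pfm_to_log_odds(
        pwm_from_consensus(cfg.canonical_consensus, cfg.motif_softness)
    )
    noncanonical_lom = pfm_to_log_odds(
        pwm_from_consensus(cfg.noncanonical_consensus, cfg.motif_softness)
    )
    rng = np.random.default_rng(cfg.seed + 1)
    n_noncanon = int(round(cfg.noncanonical_fraction * cfg.n_peaks))
    noncanon_idx = set(rng.choice(cfg.n_peaks, size=n_noncanon, replace=False).tolist())
    summit = cfg.peak_length // 2
    gap = cfg.peak_length + 50
    width = len(str(cfg.n_peaks))
    positives, decoys, truth = [], [], []
    denom = max(cfg.n_peaks - 1, 1)
    for i in range(cfg.n_peaks):
        s_i = float(np.exp(-cfg.signal_decay * i / denom))
        mismatch = min(cfg.motif_softness + 0.25 * (1.0 - s_i), 0.6)
        kind = "noncanonical" if i in noncanon_idx else "canonical"
        consensus = (
            cfg.noncanonical_consensus if kind == "noncanonical"
            else cfg.canonical_consensus
        )
        w = len(consensus)
        if kind == "noncanonical":
            # a non-canonical peak's truth label promises the canonical PWM
            # sees nothing: resample until (a) the instance is CNNG-free on
            # both strands, (b) so is its whole scan-window neighbourhood,
            # and (c) no window of the peak scores above background under
            # the canonical PWM (chance canonical-like background windows
            # would falsify the label)
            for attempt in range(500):
                peak = [
                    BASES[j] for j in _random_seq(rng, cfg.peak_length, cfg.gc_content)
                ]
                start = summit - w // 2 + int(rng.integers(-10, 11))
                start = max(0, min(start, cfg.peak_length - w))
                instance = _sample_instance(rng, consensus, mismatch)
                if iupac_contains(instance, CORE_PATTERN, both_strands=True):
                    continue
                _plant_region_core_free(
                    rng, peak, instance, start,
                    flank=cfg.read_length - w if cfg.read_length > w else 8,
                    gc=cfg.gc_content,
                )
                seq = "".join(peak)
                if best_hit(canonical_lom, seq, both_strands=True).score < 0:
                    break
            else:
                raise RuntimeError("cannot build a canonical-PWM-negative peak")
        else:
            peak = [
                BASES[j] for j in _random_seq(rng, cfg.peak_length, cfg.gc_content)
            ]
            start = summit - w // 2 + int(rng.integers(-10, 11))
            start = max(0, min(start, cfg.peak_length - w))
            instance = _sample_instance(rng, consensus, mismatch)
            peak[start : start + w] = list(instance)
            seq = "".join(peak)
        chip = 10.0 * s_i * float(np.exp(rng.normal(0.0, cfg.chip_score_noise_sd)))
        name = f"peak_{i:0{width}d}"
        positives.append(
            PeakRecord(
                chrom="chrSim", start=i * gap, end=i * gap + cfg.peak_length,
                name=name, chip_score=chip, qvalue=5.0 + chip,
                summit_offset=summit, seq=seq,
            )
        )
        truth.append(TruthRow(name, True, kind, start, s_i))

        # the decoy's truth label is "no motif": re-shuffle until neither
        # motif is locally reconstructed by chance (a shuffle of a 100-mer
        # occasionally rebuilds the planted site, which would falsify the
        # label); dinucleotide matching is preserved by every shuffle
        for _ in range(500):
            decoy_seq = dinucleotide_shuffle(seq, rng)
            if (
                best_hit(canonical_lom, decoy_seq, both_strands=True).score < 0
                and best_hit(noncanonical_lom, decoy_seq, both_strands=True).score < 0
            ):
                break
        else:
            raise RuntimeError("cannot shuffle a motif-free decoy")
        decoy_name = f"decoy_{i:0{width}d}"
        decoys.append(
            PeakRecord(
                chrom="chrSimDecoy", start=i * gap, end=i * gap + cfg.peak_length,
                name=decoy_name, chip_score=chip, qvalue=5.0 + chip,
                summit_offset=summit, seq=decoy_seq,
            )
        )
        truth.append(TruthRow(decoy_name, False, "none", None, 0.0))
    return positives, decoys, truth


def simulate_kd(
    true_strength: float,
    cfg: SyntheticConfig,
    rng: np.random.Generator | None = None,
) -> float | None:
    """Dissociation constant (µM) for a site of given strength, or None
    (censored: no binding detected) above the detection threshold.

    ``kd = kd_min * exp(kd_slope * (1 - strength))`` with optional
    multiplicative lognormal noise; monotonically decreasing in strength.
    """
    if not (0.0 <= true_strength <= 1.0):
        raise ConfigError("true_strength must be in [0, 1]")
    kd = cfg.kd_min * float(np.exp(cfg.kd_slope * (1.0 - true_strength)))
    if cfg.kd_noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng(cfg.seed)
        kd *= float(np.exp(rng.normal(0.0, cfg.kd_noise_sd)))
    return None if kd > cfg.detection_threshold else kd


#: strength grid for the default simulated affinity panel: six strengths
#: with measurable constants and three below the censoring point, mirroring
#: the 6-measured / 3-censored structure of a typical calorimetry panel
DEFAULT_PANEL_STRENGTHS: tuple[float, ...] = (
    1.0, 0.9, 0.8, 0.7, 0.6, 0.5, 0.2, 0.1, 0.05,
)


def simulate_affinity_panel(
    cfg: SyntheticConfig,
    strengths: Sequence[float] = DEFAULT_PANEL_STRENGTHS,
) -> tuple[list[SequenceRecord], list[float], list[float | None]]:
    """Ligand sequences of graded site strength with simulated Kd values.

    Each ligand is a read-length sequence carrying a canonical-motif
    instance whose per-position consensus identity is
    ``0.25 + 0.75 * strength`` (strength 1 gives the exact consensus,
    strength 0 gives background). Returns (records, strengths, kds) where a
    Kd of None is censored.
    """
    rng = np.random.default_rng(cfg.seed + 2)
    records, kds = [], []
    w = len(cfg.canonical_consensus)
    for k, s in enumerate(strengths):
        idx = _random_seq(rng, cfg.read_length, cfg.gc_content)
        seq = "".join(BASES[j] for j in idx)
        mismatch = (1.0 - s) * 0.75
        instance = _sample_instance(rng, cfg.canonical_consensus, mismatch)
        offset = int(rng.integers(cfg.read_length - w + 1))
        seq = seq[:offset] + instance + seq[offset + w :]
        records.append(SequenceRecord(id=f"ligand_{k:02d}", seq=seq))
        kds.append(simulate_kd(s, cfg, rng))
    return records, list(strengths), kds


def write_truth_tsv(truth: Sequence[TruthRow], path) -> None:
    with open(path, "w") as fh:
        fh.write("id\thas_motif\tmotif_kind\tmotif_offset\ttrue_strength\n")
        for row in truth:
            off = "" if row.motif_offset is None else str(row.motif_offset)
            fh.write(
                f"{row.id}\t{int(row.has_motif)}\t{row.motif_kind}\t{off}\t"
                f"{row.true_strength:.4f}\n"
            )
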