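"""Model assessment: ROC/PR, binned resampled-negative AUC, affinity correlation.

ROC-AUC is computed exactly as the Mann-Whitney pair statistic with midrank
tie handling (no curve interpolation); the PR area uses trapezoidal
integration over the full threshold sweep. The affinity analysis follows the
censoring rule used with isothermal-titration-calorimetry panels: Pearson on
raw (score, Kd) pairs excluding non-binders, Spearman on ranks of all
records with non-binders imputed at a fixed value just above the assay's
detection threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from crnn_tfbs.errors import DegenerateDataError, InputError
from crnn_tfbs.genome_scan import ScanResult

logger = logging.getLogger(__name__)


@dataclass
class RocResult:
    auc: float
    fpr: np.ndarray
    tpr: np.ndarray
    n_pos: int
    n_neg: int


def roc_auc(pos_scores, neg_scores) -> RocResult:
    """Exact ROC-AUC: (#{pos>neg} + 0.5 #{pos==neg}) / (n_pos * n_neg).

    Computed via midranks (the Mann-Whitney U statistic), which equals the
    pair-counting definition exactly, including ties. Curve points come from
    a threshold sweep over the pooled scores and are intended for plotting.
    """
    pos = np.asarray(pos_scores, dtype=float)
    neg = np.asarray(neg_scores, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise InputError("both score lists must be non-empty")
    pooled = np.concatenate([pos, neg])
    ranks = stats.rankdata(pooled)  # midranks
    u = ranks[: pos.size].sum() - pos.size * (pos.size + 1) / 2.0
    auc = u / (pos.size * neg.size)

    # threshold sweep (descending unique scores) for the curve
    order = np.argsort(-pooled, kind="mergesort")
    labels = np.concatenate([np.ones(pos.size), np.zeros(neg.size)])[order]
    sorted_scores = pooled[order]
    distinct = np.r_[np.diff(sorted_scores) != 0, True]
    tps = np.cumsum(labels)[distinct]
    fps = np.cumsum(1 - labels)[distinct]
    tpr = np.r_[0.0, tps / pos.size]
    fpr = np.r_[0.0, fps / neg.size]
    return RocResult(auc=float(auc), fpr=fpr, tpr=tpr, n_pos=pos.size, n_neg=neg.size)


def pr_auc(pos_scores, neg_scores) -> float:
    """Area under the precision-recall curve, trapezoid over the sweep.

    A score-free (random) classifier attains the class prevalence
    n_pos / (n_pos + n_neg).
    """
    pos = np.asarray(pos_scores, dtype=float)
    neg = np.asarray(neg_scores, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise InputError("both score lists must be non-empty")
    pooled = np.concatenate([pos, neg])
    labels = np.concatenate([np.ones(pos.size), np.zeros(neg.size)])
    order = np.argsort(-pooled, kind="mergesort")
    labels = labels[order]
    sorted_scores = pooled[order]
    distinct = np.r_[np.diff(sorted_scores) != 0, True]
    tps = np.cumsum(labels)[distinct]
    fps = np.cumsum(1 - labels)[distinct]
    precision = tps / (tps + fps)
    recall = tps / pos.size
    # prepend the first point at recall 0 with its precision
    recall = np.r_[0.0, recall]
    precision = np.r_[precision[0], precision]
    return float(np.trapezoid(precision, recall))


def bin_sizes(n: int, bin_size: int) -> list[int]:
    """Sizes of consecutive bins partitioning ``n`` items (last may be short)."""
    if n < 1 or bin_size < 1:
        raise InputError("n and bin_size must be >= 1")
    full, rem = divmod(n, bin_size)
    return [bin_size] * full + ([rem] if rem else [])


@dataclass
class BinnedAucResult:
    """Per-bin AUC under repeated random negative resampling."""

    bin_index: list[int]
    n_pos: list[int]
    mean_chip_score: list[float]
    mean_auc: list[float]
    sd_auc: list[float]
    per_repeat_auc: np.ndarray  # (n_bins, repeats)
    repeats: int
    n_neg_per_repeat: int


def binned_auc(
    pos_results: Sequence[ScanResult],
    neg_results: Sequence[ScanResult],
    bin_size: int = 500,
    n_neg: int = 500,
    repeats: int = 1000,
    seed: int = 0,
) -> BinnedAucResult:
    """AUC per ChIP-score bin against resampled negative peaks.

    Positive peaks are sorted by decreasing ChIP score and cut into
    consecutive bins of ``bin_size`` (the last bin may be smaller). For each
    bin and repeat, ``n_neg`` negatives are drawn uniformly without
    replacement and the exact ROC-AUC computed; the mean/sd over repeats is
    reported per bin together with its mean ChIP score.
    """
    if len(neg_results) < n_neg:
        raise InputError(
            f"need at least {n_neg} negatives, got {len(neg_results)}"
        )
    if any(r.chip_score is None for r in pos_results):
        raise InputError("positive results must carry chip scores")
    rng = np.random.default_rng(seed)
    pos_sorted = sorted(pos_results, key=lambda r: -r.chip_score)
    neg_scores = np.array([r.score for r in neg_results], dtype=float)
    sizes = bin_sizes(len(pos_sorted), bin_size)

    res = BinnedAucResult(
        bin_index=[], n_pos=[], mean_chip_score=[], mean_auc=[], sd_auc=[],
        per_repeat_auc=np.empty((len(sizes), repeats)),
        repeats=repeats, n_neg_per_repeat=n_neg,
    )
    start = 0
    for b, size in enumerate(sizes):
        chunk = pos_sorted[start : start + size]
        start += size
        pos_scores = np.array([r.score for r in chunk], dtype=float)
        for rep in range(repeats):
            drawn = rng.choice(neg_scores.size, size=n_neg, replace=False)
            res.per_repeat_auc[b, rep] = roc_auc(pos_scores, neg_scores[drawn]).auc
        res.bin_index.append(b)
        res.n_pos.append(size)
        res.mean_chip_score.append(float(np.mean([r.chip_score for r in chunk])))
        res.mean_auc.append(float(res.per_repeat_auc[b].mean()))
        res.sd_auc.append(float(res.per_repeat_auc[b].std(ddof=1)) if repeats > 1 else 0.0)
    return res


def score_distribution_summary(
    results_by_dataset: Mapping[str, Sequence[ScanResult]],
    flag_ids: Sequence[str] = (),
) -> dict[str, dict]:
    """Quartiles and histograms per dataset, with optional flagged peaks.

    Flagged ids absent from every dataset produce an explicit warning entry
    rather than a silent omission.
    """
    summary: dict[str, dict] = {}
    seen_flags: set[str] = set()
    for name, results in results_by_dataset.items():
        if not results:
            raise InputError(f"dataset {name!r} has no results")
        scores = np.array([r.score for r in results], dtype=float)
        q = np.percentile(scores, [0, 25, 50, 75, 100])
        hist, edges = np.histogram(scores, bins=20)
        flagged = {}
        for fid in flag_ids:
            for r in results:
                if r.peak_id == fid:
                    flagged[fid] = {"score": r.score, "percentile": r.percentile}
                    seen_flags.add(fid)
        summary[name] = {
            "n": int(scores.size),
            "min": float(q[0]), "q1": float(q[1]), "median": float(q[2]),
            "q3": float(q[3]), "max": float(q[4]),
            "histogram": hist.tolist(),
            "bin_edges": edges.tolist(),
            "flagged": flagged,
        }
    for fid in flag_ids:
        if fid not in seen_flags:
            logger.warning("flagged id %r not present in any dataset", fid)
            summary.setdefault("_missing_flags", {}).setdefault("ids", []).append(fid)
    return summary


# ---------------------------------------------------------------------------
# Affinity correlation


@dataclass(frozen=True)
class AffinityRecord:
    """A ligand sequence with its measured dissociation constant.

    ``kd`` is in µM; ``None`` marks a censored measurement (no binding
    detected at the assay's threshold). Thermodynamic columns are carried
    for reporting but never computed here.
    """

    ligand_id: str
    sequence: str
    kd: float | None
    dh: float | None = None
    minus_tds: float | None = None
    dg: float | None = None

    def __post_init__(self) -> None:
        if self.kd is not None and self.kd <= 0:
            raise InputError(f"{self.ligand_id}: Kd must be > 0 when present")

    @property
    def censored(self) -> bool:
        return self.kd is None


@dataclass
class AffinityCorrelation:
    pearson_r: float | None
    r_squared: float | None
    spearman_rho: float
    n_used_pearson: int
    n_used_spearman: int
    censored_value: float
    notes: list[str]

    @property
    def pearson_abs(self) -> float | None:
        return None if self.pearson_r is None else abs(self.pearson_r)

    @property
    def spearman_abs(self) -> float:
        return abs(self.spearman_rho)


def affinity_correlation(
    scores: Mapping[str, float],
    affinities: Sequence[AffinityRecord],
    censored_value: float = 10.0,
) -> AffinityCorrelation:
    """Correlate predicted binding scores with measured Kd values.

    Pearson is computed on raw (score, Kd) pairs *excluding* censored
    records; Spearman is computed on ranks of *all* records with censored
    Kd imputed at ``censored_value`` (default 10 µM, one unit above a 9 µM
    detection threshold). Signed coefficients are reported; strong binding
    means low Kd at high score, so a negative sign is the expected direction.
    """
    missing = [a.ligand_id for a in affinities if a.ligand_id not in scores]
    if missing:
        raise InputError(f"no score for ligands: {missing}")
    if len(affinities) < 3:
        raise InputError("need at least 3 affinity records")
    notes: list[str] = []

    uncensored = [a for a in affinities if not a.censored]
    pearson_r: float | None = None
    r_squared: float | None = None
    if len(uncensored) >= 3:
        xs = np.array([scores[a.ligand_id] for a in uncensored])
        ys = np.array([a.kd for a in uncensored], dtype=float)
        if np.ptp(xs) == 0 or np.ptp(ys) == 0:
            raise DegenerateDataError(
                "Pearson undefined: zero variance in scores or Kd values"
            )
        pearson_r = float(stats.pearsonr(xs, ys).statistic)
        r_squared = pearson_r**2
    else:
        notes.append(
            f"only {len(uncensored)} uncensored pairs (< 3); Pearson not computed"
        )

    xs_all = np.array([scores[a.ligand_id] for a in affinities])
    ys_all = np.array(
        [censored_value if a.censored else a.kd for a in affinities], dtype=float
    )
    if np.ptp(xs_all) == 0 or np.ptp(ys_all) == 0:
        raise DegenerateDataError("Spearman undefined: zero variance after imputation")
    spearman_rho = float(stats.spearmanr(xs_all, ys_all).statistic)

    return AffinityCorrelation(
        pearson_r=pearson_r,
        r_squared=r_squared,
        spearman_rho=spearman_rho,
        n_used_pearson=len(uncensored) if pearson_r is not None else 0,
        n_used_spearman=len(affinities),
        censored_value=censored_value,
        notes=notes,
    )


def parse_affinity_table(text: str) -> list[AffinityRecord]:
    """Parse a ligand table: ligand_id, sequence, kd_uM (or NBD), dH, -TdS, dG."""
    lines = text.splitlines()
    if not lines or lines[0].split("\t")[:3] != ["ligand_id", "sequence", "kd_uM"]:
        raise InputError("expected columns ligand_id/sequence/kd_uM...")
    records = []
    for line in lines[1:]:
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3 or not parts[0]:
            continue
        kd = None if parts[2].upper() == "NBD" else float(parts[2])
        opt = [
            float(parts[i]) if len(parts) > i and parts[i] not in ("", "-") else None
            for i in (3, 4, 5)
        ]
        records.append(
            AffinityRecord(
                ligand_id=parts[0], sequence=parts[1], kd=kd,
                dh=opt[0], minus_tds=opt[1], dg=opt[2],
            )
        )
    return records


def read_affinity_tsv(path) -> list[AffinityRecord]:
    with open(path) as fh:
        return parse_affinity_table(fh.read())
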