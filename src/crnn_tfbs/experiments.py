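"""End-to-end study-condition experiments on the synthetic generators.

These functions wire the pipeline stages together under the package's
default study conditions (the :class:`~crnn_tfbs.synthdata.SyntheticConfig`
defaults): train the default classifier on planted-motif reads vs. their
dinucleotide shuffles, run the label-permutation control, the non-canonical
discovery experiment on peak windows, and the affinity-correlation panel.
Both the test suite and the reproduction script call these, so reported
numbers always come from the same code path.

All randomness derives from a single integer seed; sub-seeds are fixed
offsets so the stages stay independent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

from crnn_tfbs.crnn import BindingClassifier, BindingFitResults, ModelConfig
from crnn_tfbs.evaluate import (
    AffinityCorrelation,
    AffinityRecord,
    affinity_correlation,
    roc_auc,
)
from crnn_tfbs.genome_scan import discover_noncanonical, filter_peaks, scan_all
from crnn_tfbs.negatives import (
    BINDING,
    NON_BINDING,
    LabelledDataset,
    build_balanced_dataset,
    split_dataset,
)
from crnn_tfbs.pwmscore import best_hit, pfm_to_log_odds
from crnn_tfbs.seqio import SequenceRecord, iupac_contains
from crnn_tfbs.synthdata import (
    SyntheticConfig,
    pwm_from_consensus,
    simulate_affinity_panel,
    simulate_peaks,
    simulate_reads,
)


@dataclass
class ReadExperiment:
    """Trained default model plus the datasets and held-out performance."""

    model: BindingClassifier
    fit: BindingFitResults
    train: LabelledDataset
    val: LabelledDataset
    test: LabelledDataset
    test_auc: float


def train_default_model(
    seed: int = 0, synth: SyntheticConfig | None = None,
    model_config: ModelConfig | None = None,
) -> ReadExperiment:
    """Simulate reads at default conditions, build shuffles, split, train.

    The default read count (7,200 positives, so 14,400 labelled records)
    yields roughly 10,000 training and 2,000 validation records at the
    70/15/15 split.
    """
    scfg = synth if synth is not None else SyntheticConfig(seed=seed)
    reads, _ = simulate_reads(scfg)
    dataset = build_balanced_dataset(reads, seed=seed + 101)
    train, val, test = split_dataset(dataset, seed=seed + 202)
    cfg = model_config if model_config is not None else ModelConfig(seed=seed + 303)
    model = BindingClassifier(cfg)
    fit = model.fit(train, val)
    if cfg.use_conv:
        # parameter-recovery diagnostic: top-activating windows of the
        # strongest filter vs. the planted consensus (logged, never asserted)
        positives = [r.seq for r, lab in train.records if lab == "binding"][:200]
        diag = model.filter_motif_summary(positives, scfg.canonical_consensus)
        logger.info("best-filter motif diagnostic: %s", diag)
    scores = model.predict([rec for rec, _ in test.records])
    y = test.labels()
    test_auc = roc_auc(scores[y == 1], scores[y == 0]).auc
    return ReadExperiment(
        model=model, fit=fit, train=train, val=val, test=test, test_auc=test_auc
    )


def permute_labels(dataset: LabelledDataset, seed: int) -> LabelledDataset:
    """Random reassignment of the dataset's labels (class counts preserved)."""
    rng = np.random.default_rng(seed)
    labels = [lab for _, lab in dataset.records]
    perm = rng.permutation(len(labels))
    return LabelledDataset(
        records=[
            (rec, labels[perm[i]]) for i, (rec, _) in enumerate(dataset.records)
        ]
    )


def label_permutation_control(
    train: LabelledDataset, val: LabelledDataset,
    seed: int = 0, model_config: ModelConfig | None = None,
) -> float:
    """Validation AUC after destroying the label-sequence association.

    Chance-level performance (about 0.5) certifies that nothing except the
    labels carries signal — in particular that a read and its shuffle do
    not leak composition information across the split.
    """
    cfg = model_config if model_config is not None else ModelConfig(seed=seed + 404)
    model = BindingClassifier(cfg)
    fit = model.fit(
        permute_labels(train, seed + 505), permute_labels(val, seed + 606)
    )
    return fit.validation_auc


@dataclass
class DiscoveryExperiment:
    n_noncanonical: int
    n_recovered: int
    recall: float
    n_background_selected: int
    n_canonical_selected: int
    cnng_free_fraction: float
    hits: list


def discovery_experiment(
    model: BindingClassifier,
    seed: int = 0,
    synth: SyntheticConfig | None = None,
    rnn_min: float = 0.99,
    pwm_max: float = 0.0,
) -> DiscoveryExperiment:
    """Non-canonical site discovery on synthetic peaks plus matched decoys.

    Both the planted-site peaks and their dinucleotide-shuffled decoys are
    scanned with the neural model (forward strand, stride 1) and with the
    canonical-motif PWM (both strands); the filter keeps peaks the model
    calls binding (score > ``rnn_min``) that the PWM calls non-binding
    (best log-odds < ``pwm_max``). Recovery is measured against the
    generator's truth table; decoy selections count as false discoveries.
    """
    scfg = synth if synth is not None else SyntheticConfig(seed=seed)
    positives, decoys, truth = simulate_peaks(scfg)
    positives = filter_peaks(positives, 1e-5)
    lom = pfm_to_log_odds(
        pwm_from_consensus(scfg.canonical_consensus, scfg.motif_softness)
    )
    window = model.config.input_length

    def pwm_scorer(windows):
        return np.array([best_hit(lom, w, both_strands=True).score for w in windows])

    results = {}
    for name, peaks in (("pos", positives), ("decoy", decoys)):
        seqs = [SequenceRecord(id=p.name, seq=p.seq) for p in peaks]
        rnn_res = scan_all(model.score_windows, seqs, window)
        pwm_res = scan_all(pwm_scorer, seqs, window)
        results[name] = discover_noncanonical(rnn_res, pwm_res, rnn_min, pwm_max)

    noncanon_ids = {r.id for r in truth if r.motif_kind == "noncanonical"}
    recovered = [h for h in results["pos"] if h.peak_id in noncanon_ids]
    canonical_sel = [h for h in results["pos"] if h.peak_id not in noncanon_ids]
    cnng_free = [
        not iupac_contains(h.rnn_window, "CNNG", both_strands=True) for h in recovered
    ]
    return DiscoveryExperiment(
        n_noncanonical=len(noncanon_ids),
        n_recovered=len(recovered),
        recall=len(recovered) / len(noncanon_ids) if noncanon_ids else float("nan"),
        n_background_selected=len(results["decoy"]),
        n_canonical_selected=len(canonical_sel),
        cnng_free_fraction=(
            sum(cnng_free) / len(cnng_free) if cnng_free else float("nan")
        ),
        hits=results["pos"],
    )


@dataclass
class AffinityExperiment:
    correlation: AffinityCorrelation
    n_censored: int
    records: list[AffinityRecord]
    scores: dict[str, float]


def affinity_experiment(
    model: BindingClassifier,
    seed: int = 0,
    synth: SyntheticConfig | None = None,
    censored_value: float = 10.0,
) -> AffinityExperiment:
    """Correlate model scores with simulated dissociation constants.

    The default panel carries six ligands with measurable Kd and three
    censored below the detection threshold; censored values are imputed at
    ``censored_value`` for the rank correlation and excluded from Pearson.
    """
    scfg = synth if synth is not None else SyntheticConfig(seed=seed)
    ligands, _, kds = simulate_affinity_panel(scfg)
    records = [
        AffinityRecord(ligand_id=rec.id, sequence=rec.seq, kd=kd)
        for rec, kd in zip(ligands, kds)
    ]
    scores = dict(zip([r.ligand_id for r in records], map(float, model.predict(ligands))))
    corr = affinity_correlation(scores, records, censored_value=censored_value)
    return AffinityExperiment(
        correlation=corr,
        n_censored=sum(r.censored for r in records),
        records=records,
        scores=scores,
    )
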