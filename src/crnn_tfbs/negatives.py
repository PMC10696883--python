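"""Dinucleotide-preserving shuffle negatives and balanced dataset assembly.

The shuffle is the Altschul-Erickson Eulerian-walk construction (the
algorithm behind MEME's ``fasta-shuffle-letters`` at k=2): the output has
exactly the same multiset of overlapping dinucleotides as the input — hence
identical mononucleotide counts and GC content — and keeps the first and
last base fixed. Shuffled copies of binding reads serve as non-binding
controls when training the classifier, forcing it to learn base *order*
rather than composition.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from crnn_tfbs.errors import AlphabetError, InputError
from crnn_tfbs.seqio import BASES, SequenceRecord

Label = Literal["binding", "non_binding"]

BINDING: Label = "binding"
NON_BINDING: Label = "non_binding"


@dataclass
class LabelledDataset:
    """Sequence records with binding / non-binding labels."""

    records: list[tuple[SequenceRecord, Label]]

    @property
    def class_counts(self) -> dict[Label, int]:
        counts: dict[Label, int] = {BINDING: 0, NON_BINDING: 0}
        for _, label in self.records:
            counts[label] += 1
        return counts

    def __len__(self) -> int:
        return len(self.records)

    def sequences(self) -> list[str]:
        return [rec.seq for rec, _ in self.records]

    def labels(self) -> np.ndarray:
        return np.array([1 if lab == BINDING else 0 for _, lab in self.records])

    def subset(self, indices: Sequence[int]) -> "LabelledDataset":
        return LabelledDataset(records=[self.records[i] for i in indices])


def dinucleotide_counts(seq: str) -> np.ndarray:
    """16-vector of overlapping dinucleotide counts (AA,AC,...,TT order)."""
    counts = np.zeros(16, dtype=np.int64)
    idx = {b: i for i, b in enumerate(BASES)}
    for a, b in zip(seq, seq[1:]):
        counts[idx[a] * 4 + idx[b]] += 1
    return counts


def _derive_rng(seed: int, record_id: str) -> np.random.Generator:
    """Per-record stream from a top-level seed, stable under reordering."""
    digest = hashlib.sha256(f"{seed}:{record_id}".encode()).digest()
    return np.random.default_rng(int.from_bytes(digest[:8], "little"))


def dinucleotide_shuffle(seq: str, rng: np.random.Generator) -> str:
    """Shuffle ``seq`` preserving its overlapping-dinucleotide multiset.

    Altschul-Erickson construction: view the sequence as an Eulerian path
    in the multigraph whose edges are its dinucleotides; sample a random
    in-tree toward the terminal base to fix each vertex's final exit edge,
    shuffle the remaining edge lists, and walk. First and last characters
    always equal the input's.
    """
    seq = seq.upper()
    bad = set(seq) - set(BASES)
    if bad:
        raise AlphabetError(f"shuffle input restricted to A,C,G,T; found {sorted(bad)!r}")
    if len(seq) < 3:
        raise InputError("sequences shorter than 3 nt have no nontrivial shuffle")

    last = seq[-1]
    # adjacency: vertex -> list of successor vertices (edge multiset)
    adj: dict[str, list[str]] = {}
    for a, b in zip(seq, seq[1:]):
        adj.setdefault(a, []).append(b)
    vertices = [v for v in BASES if v in adj or v == last]

    # choose each non-terminal vertex's LAST outgoing edge so that following
    # last-edges from any vertex reaches `last` (the chosen edges form an
    # in-tree); rejection-sample until connected
    nonterminal = [v for v in vertices if v != last and adj.get(v)]
    while True:
        last_edge = {v: adj[v][rng.integers(len(adj[v]))] for v in nonterminal}
        ok = True
        for v in nonterminal:
            cur, hops = v, 0
            while cur != last:
                if cur not in last_edge or hops > 4:
                    ok = False
                    break
                cur = last_edge[cur]
                hops += 1
            if not ok:
                break
        if ok:
            break

    # shuffle remaining edges; append the reserved last edge at the end
    shuffled: dict[str, list[str]] = {}
    for v, targets in adj.items():
        pool = list(targets)
        if v in last_edge:
            pool.remove(last_edge[v])
        pool = [pool[i] for i in rng.permutation(len(pool))]
        if v in last_edge:
            pool.append(last_edge[v])
        shuffled[v] = pool

    # Eulerian walk from the original first character
    out = [seq[0]]
    ptr = {v: 0 for v in shuffled}
    cur = seq[0]
    for _ in range(len(seq) - 1):
        nxt = shuffled[cur][ptr[cur]]
        ptr[cur] += 1
        out.append(nxt)
        cur = nxt
    return "".join(out)


def build_balanced_dataset(
    positives: Sequence[SequenceRecord],
    seed: int = 0,
) -> LabelledDataset:
    """One dinucleotide-shuffled negative per positive, labels attached.

    Negative ids are ``<source_id>_shuf``; per-record RNG streams are derived
    by stable hashing of the record id so results do not depend on
    collection order.
    """
    if not positives:
        raise InputError("positives must be non-empty")
    lengths = {r.length for r in positives}
    if len(lengths) != 1:
        raise InputError(f"all positives must share one length; saw {sorted(lengths)}")
    records: list[tuple[SequenceRecord, Label]] = []
    for rec in positives:
        if "N" in rec.seq:
            raise InputError(f"record {rec.id!r} contains N; reads with N are rejected")
        rng = _derive_rng(seed, rec.id)
        shuf = dinucleotide_shuffle(rec.seq, rng)
        records.append((rec, BINDING))
        records.append((SequenceRecord(id=f"{rec.id}_shuf", seq=shuf), NON_BINDING))
    return LabelledDataset(records=records)


def split_dataset(
    dataset: LabelledDataset,
    ratios: tuple[float, float, float] = (0.70, 0.15, 0.15),
    seed: int = 0,
) -> tuple[LabelledDataset, LabelledDataset, LabelledDataset]:
    """Random train/validation/test partition, stratified and leakage-safe.

    A positive and its derived ``_shuf`` negative are always co-assigned to
    the same subset: a shuffle in the test set whose source read was trained
    on would leak composition information. Units (pairs, or single records
    when unpaired) are permuted; validation and test take
    ``floor(n_units * ratio)`` units each and the remainder goes to train.
    """
    if any(r <= 0 for r in ratios) or abs(sum(ratios) - 1.0) > 1e-9:
        raise InputError(f"ratios must be positive and sum to 1, got {ratios}")

    by_id = {rec.id: i for i, (rec, _) in enumerate(dataset.records)}
    used: set[int] = set()
    units: list[list[int]] = []
    for i, (rec, label) in enumerate(dataset.records):
        if i in used:
            continue
        unit = [i]
        used.add(i)
        if label == BINDING and f"{rec.id}_shuf" in by_id:
            j = by_id[f"{rec.id}_shuf"]
            if j not in used:
                unit.append(j)
                used.add(j)
        units.append(unit)

    rng = np.random.default_rng(seed)
    order = rng.permutation(len(units))
    n_val = int(len(units) * ratios[1])
    n_test = int(len(units) * ratios[2])
    n_train = len(units) - n_val - n_test
    if min(n_train, n_val, n_test) < 1:
        raise InputError(
            f"{len(units)} units cannot fill all three subsets at ratios {ratios}"
        )
    train_u = order[:n_train]
    val_u = order[n_train : n_train + n_val]
    test_u = order[n_train + n_val :]

    def gather(unit_idx) -> LabelledDataset:
        idx = [i for u in unit_idx for i in units[u]]
        return dataset.subset(sorted(idx))

    return gather(train_u), gather(val_u), gather(test_u)


def write_dataset_tsv(dataset: LabelledDataset, path) -> None:
    """Serialize as TSV with columns id, sequence, label."""
    with open(path, "w") as fh:
        fh.write("id\tsequence\tlabel\n")
        for rec, label in dataset.records:
            fh.write(f"{rec.id}\t{rec.seq}\t{label}\n")


def read_dataset_tsv(path) -> LabelledDataset:
    records: list[tuple[SequenceRecord, Label]] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["id", "sequence", "label"]:
            raise InputError(f"{path}: expected header id/sequence/label")
        for line in fh:
            rid, seq, label = line.rstrip("\n").split("\t")
            if label not in (BINDING, NON_BINDING):
                raise InputError(f"{path}: unknown label {label!r}")
            records.append((SequenceRecord(id=rid, seq=seq), label))  # type: ignore[arg-type]
    return LabelledDataset(records=records)
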