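"""Training protocol: leakage-aware splitting, per-epoch contig resampling,
1:1 negative construction, binary cross-entropy with early stopping.

The unit of supervision is an association pair (phage id, host id, label).
Contigs are *not* fixed inputs: at the start of every epoch, for every batch
one phage length and one host length are drawn from the configured menus and
fresh substrings are sampled from the underlying genomes, so the network
sees a different rendering of each association every epoch.  Negative pairs
are re-drawn each epoch as well, pairing each positive's phage with a host
that has no recorded association with it, at a 1:1 ratio.

Splitting guards against two leakage channels: near-identical phage genomes
(handled through an externally produced sequence-cluster map — one
representative phage per cluster) and shared host taxa (any training pair
whose phage cluster or host taxon also occurs in validation is moved to
validation, iterated to a fixed point).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np

from . import nn
from ._rng import child_rng
from .encoding import ContigRecord, Role
from .evaluation import compute_auroc
from .io import read_fasta
from .model import AssociationModel

logger = logging.getLogger(__name__)

__all__ = [
    "AssociationPair",
    "TrainConfig",
    "SplitSpec",
    "GenomeStore",
    "split_pairs",
    "sample_contig",
    "make_negative",
    "train",
    "grid_search",
]


@dataclass(frozen=True)
class AssociationPair:
    """(phage id, host id, label) — label 1 for a recorded association."""

    phage_id: str
    host_id: str
    label: int = 1

    def __post_init__(self) -> None:
        if self.label not in (0, 1):
            raise ValueError("label must be 0 or 1")


@dataclass(frozen=True)
class TrainConfig:
    """Optimization and sampling hyperparameters.

    Defaults follow the grid-searched operating point (learning rate 1e-3,
    batch size 32) and the standard contig-length menus: phage lengths
    200 bp – 50 kb and host lengths 200 bp – 100 kb.  Early stopping halts
    when the monitored validation loss fails to improve by
    ``early_stop_delta`` for ``early_stop_patience`` consecutive epochs.
    """

    learning_rate: float = 0.001
    batch_size: int = 32
    max_epochs: int = 5000
    early_stop_delta: float = 0.00001
    early_stop_patience: int = 50
    phage_length_menu: Tuple[int, ...] = (200, 500, 1000, 5000, 10000, 50000)
    host_length_menu: Tuple[int, ...] = (200, 500, 1000, 5000, 10000, 50000, 100000)
    negatives_per_positive: int = 1
    center_head_init: bool = True
    plateau_restart_epochs: int = 8
    max_restarts: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.phage_length_menu or not self.host_length_menu:
            raise ValueError("length menus must be non-empty")
        object.__setattr__(self, "phage_length_menu", tuple(self.phage_length_menu))
        object.__setattr__(self, "host_length_menu", tuple(self.host_length_menu))

    @classmethod
    def desk_scale(cls, **overrides) -> "TrainConfig":
        """Short-contig, few-epoch settings for laptop-scale experiments."""
        base = dict(learning_rate=0.003, max_epochs=30, early_stop_patience=30,
                    phage_length_menu=(200, 500, 1000),
                    host_length_menu=(200, 500, 1000))
        base.update(overrides)
        return cls(**base)


@dataclass(frozen=True)
class SplitSpec:
    """How to divide pairs into train/validation without sequence leakage."""

    cluster_of: Mapping[str, str]
    train_fraction: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.train_fraction < 1.0):
            raise ValueError("train_fraction must be in (0, 1)")


class GenomeStore:
    """Maps an id (phage genome or host species) to one or more genome sequences.

    A host species may carry several assemblies; sampling draws one
    uniformly per call, so a host is represented by a rotating assembly
    rather than a fixed one.
    """

    def __init__(self) -> None:
        self._genomes: Dict[str, List[str]] = {}

    def add(self, key: str, sequence: str) -> None:
        if not sequence:
            raise ValueError(f"genome {key!r}: empty sequence")
        self._genomes.setdefault(key, []).append(sequence)

    def keys(self) -> List[str]:
        return list(self._genomes)

    def __contains__(self, key: str) -> bool:
        return key in self._genomes

    def n_assemblies(self, key: str) -> int:
        return len(self._genomes[key])

    def sample_genome(self, key: str, rng: np.random.Generator) -> str:
        seqs = self._genomes[key]
        return seqs[rng.integers(len(seqs))] if len(seqs) > 1 else seqs[0]

    @classmethod
    def from_records(cls, records: Iterable[ContigRecord]) -> "GenomeStore":
        store = cls()
        for rec in records:
            store.add(rec.id, rec.sequence)
        return store

    @classmethod
    def from_fasta_dir(cls, directory, mapping: Optional[Mapping[str, str]] = None,
                       role: Role = Role.HOST) -> "GenomeStore":
        """Load every FASTA file under ``directory``.

        ``mapping`` (record id -> store key) groups records under shared
        keys, e.g. several assemblies of one host species; unmapped records
        are keyed by their own id.
        """
        store = cls()
        paths = sorted(Path(directory).glob("*.fa*"))
        if not paths:
            raise FileNotFoundError(f"no FASTA files under {directory}")
        for p in paths:
            for rec in read_fasta(p, role=role):
                key = mapping.get(rec.id, rec.id) if mapping else rec.id
                store.add(key, rec.sequence)
        return store


# ---------------------------------------------------------------------------
# splitting


def split_pairs(pairs: Sequence[AssociationPair], split: SplitSpec,
                host_rank_of: Mapping[str, str],
                ) -> Tuple[List[AssociationPair], List[AssociationPair]]:
    """Divide positive pairs into train/validation with no cluster or taxon leakage.

    Steps: (1) one phage per sequence cluster is randomly chosen as the
    representative and every pair is re-keyed to it; (2) the de-duplicated
    pairs are split ``train_fraction`` / rest at random; (3) any training
    pair whose phage cluster or host taxon also appears in validation is
    moved to validation, repeated until no such pair remains.  The result
    has disjoint phage-cluster sets and disjoint host-taxon sets.
    """
    missing_clusters = sorted({p.phage_id for p in pairs} - set(split.cluster_of))
    if missing_clusters:
        raise ValueError(f"phage ids missing from cluster map: {missing_clusters}")
    missing_taxa = sorted({p.host_id for p in pairs} - set(host_rank_of))
    if missing_taxa:
        raise ValueError(f"host ids missing from taxon map: {missing_taxa}")

    rng = child_rng(split.seed, "split_pairs")

    # one representative phage per cluster
    members: Dict[str, List[str]] = {}
    for pid in sorted({p.phage_id for p in pairs}):
        members.setdefault(split.cluster_of[pid], []).append(pid)
    representative = {cl: ms[rng.integers(len(ms))] for cl, ms in sorted(members.items())}
    rep_of = {pid: representative[split.cluster_of[pid]] for pid in
              {p.phage_id for p in pairs}}

    deduped = sorted({AssociationPair(rep_of[p.phage_id], p.host_id, 1)
                      for p in pairs},
                     key=lambda p: (p.phage_id, p.host_id))

    order = rng.permutation(len(deduped))
    n_train = int(round(split.train_fraction * len(deduped)))
    train = [deduped[i] for i in sorted(order[:n_train])]
    val = [deduped[i] for i in sorted(order[n_train:])]

    # move leaking training pairs to validation until stable
    while True:
        val_clusters = {split.cluster_of[p.phage_id] for p in val}
        val_taxa = {host_rank_of[p.host_id] for p in val}
        moved = [p for p in train
                 if split.cluster_of[p.phage_id] in val_clusters
                 or host_rank_of[p.host_id] in val_taxa]
        if not moved:
            break
        moved_set = set(moved)
        train = [p for p in train if p not in moved_set]
        val = val + moved
    if not train:
        logger.warning("split_pairs: training set is empty after leakage removal")
    return train, val


# ---------------------------------------------------------------------------
# sampling


def sample_contig(genome: str, length: int, rng: np.random.Generator) -> str:
    """Uniform-start substring of ``length`` bases; whole genome if shorter."""
    if not genome:
        raise ValueError("cannot sample a contig from an empty genome")
    if len(genome) <= length:
        logger.debug("genome length %d <= requested %d; returning whole genome",
                     len(genome), length)
        return genome
    start = int(rng.integers(len(genome) - length + 1))
    return genome[start:start + length]


def make_negative(positive: AssociationPair, host_pool: Sequence[str],
                  positives_index: Mapping[str, Set[str]],
                  rng: np.random.Generator) -> AssociationPair:
    """Pair the positive's phage with a uniformly drawn non-associated host."""
    known = positives_index.get(positive.phage_id, set())
    candidates = [h for h in host_pool if h not in known]
    if not candidates:
        raise ValueError(
            f"phage {positive.phage_id!r} has recorded positives with every host")
    host = candidates[int(rng.integers(len(candidates)))]
    return AssociationPair(positive.phage_id, host, 0)


def build_positives_index(pairs: Iterable[AssociationPair]) -> Dict[str, Set[str]]:
    index: Dict[str, Set[str]] = {}
    for p in pairs:
        if p.label == 1:
            index.setdefault(p.phage_id, set()).add(p.host_id)
    return index


def _draw_epoch_samples(positives: Sequence[AssociationPair],
                        store: GenomeStore, host_pool: Sequence[str],
                        positives_index: Mapping[str, Set[str]],
                        config: TrainConfig, rng: np.random.Generator,
                        ) -> List[Tuple[List[str], List[str], np.ndarray]]:
    """One epoch's batches: positives + fresh 1:1 negatives, fresh contigs.

    Returns a list of (phage_sequences, host_sequences, labels) batches;
    each batch shares one phage length and one host length.
    """
    epoch_pairs = list(positives)
    for p in positives:
        for _ in range(config.negatives_per_positive):
            epoch_pairs.append(make_negative(p, host_pool, positives_index, rng))
    order = rng.permutation(len(epoch_pairs))
    batches = []
    for s in range(0, len(epoch_pairs), config.batch_size):
        chunk = [epoch_pairs[i] for i in order[s:s + config.batch_size]]
        Lp = int(config.phage_length_menu[rng.integers(len(config.phage_length_menu))])
        Lh = int(config.host_length_menu[rng.integers(len(config.host_length_menu))])
        pseqs = [sample_contig(store.sample_genome(p.phage_id, rng), Lp, rng)
                 for p in chunk]
        hseqs = [sample_contig(store.sample_genome(p.host_id, rng), Lh, rng)
                 for p in chunk]
        labels = np.array([p.label for p in chunk], dtype=np.float32)
        batches.append((pseqs, hseqs, labels))
    return batches


def _eval_batches(model: AssociationModel, batches) -> Tuple[float, float]:
    """(mean BCE loss, AUROC) over pre-sampled batches."""
    losses, scores, labels = [], [], []
    for pseqs, hseqs, y in batches:
        pi = model.encode_inputs(pseqs)
        hi = model.encode_inputs(hseqs)
        logits = model.forward_pair_batch(pi, hi)
        loss, _ = nn.bce_with_logits(logits, y)
        losses.append(loss * len(y))
        scores.extend(nn.sigmoid(logits))
        labels.extend(y)
    n = sum(len(b[2]) for b in batches)
    loss = sum(losses) / n
    labels_arr = np.asarray(labels)
    auroc = (compute_auroc(np.asarray(scores), labels_arr)
             if 0 < labels_arr.sum() < len(labels_arr) else float("nan"))
    return loss, auroc


def _reinitialize(model: AssociationModel, seed: int) -> None:
    """Overwrite all parameters with a fresh draw from ``seed`` in place."""
    from dataclasses import replace as dc_replace

    fresh = AssociationModel(dc_replace(model.config, seed=seed))
    for (_, p), (_, q) in zip(model.named_params(), fresh.named_params()):
        p.value[...] = q.value


def _center_from_batches(model: AssociationModel, batches) -> None:
    feats = []
    for pseqs, hseqs, _y in batches[:4]:
        pf = model.features_batch(model.encode_inputs(pseqs), "phage")
        hf = model.features_batch(model.encode_inputs(hseqs), "host")
        feats.append(np.concatenate([pf, hf], axis=1))
    model.center_head_biases(np.concatenate(feats, axis=0))


def train(model: AssociationModel, train_pairs: Sequence[AssociationPair],
          store: GenomeStore, config: TrainConfig,
          validation_pairs: Optional[Sequence[AssociationPair]] = None,
          host_pool: Optional[Sequence[str]] = None,
          ) -> Tuple[AssociationModel, Dict[str, list]]:
    """Optimize the model on association pairs with per-epoch resampling.

    ``train_pairs`` (and ``validation_pairs``) are positives; negatives are
    constructed fresh each epoch at the configured 1:1 ratio.  The monitored
    quantity for early stopping is the validation loss on a fixed,
    once-sampled validation rendering; validation AUROC is logged alongside.
    The model is restored to its best-validation-loss parameters before
    returning.

    Returns the trained model and a history dict with per-epoch
    ``train_loss``, ``val_loss``, ``val_auroc``, plus ``best_epoch`` and
    ``stopped_epoch``.
    """
    positives = [p for p in train_pairs if p.label == 1]
    if not positives:
        raise ValueError("no positive training pairs")
    rng = child_rng(config.seed, "train")
    if host_pool is None:
        host_pool = sorted({p.host_id for p in train_pairs}
                           | {p.host_id for p in (validation_pairs or [])})
    host_pool = sorted(host_pool)
    index = build_positives_index(list(train_pairs) + list(validation_pairs or []))

    val_batches = None
    if validation_pairs:
        val_rng = child_rng(config.seed, "validation")
        val_pos = [p for p in validation_pairs if p.label == 1]
        val_batches = _draw_epoch_samples(val_pos, store, host_pool, index,
                                          config, val_rng)

    if config.center_head_init:
        cal_rng = child_rng(config.seed, "head_init")
        _center_from_batches(model, _draw_epoch_samples(
            positives, store, host_pool, index, config, cal_rng))

    opt = nn.Adam(model.params(), lr=config.learning_rate)
    history: Dict[str, list] = {"train_loss": [], "val_loss": [], "val_auroc": []}
    restarts = 0
    best_loss = math.inf
    best_state = None
    wait = 0
    stopped_epoch = config.max_epochs

    for epoch in range(config.max_epochs):
        batches = _draw_epoch_samples(positives, store, host_pool, index,
                                      config, rng)
        epoch_loss, n_seen = 0.0, 0
        for pseqs, hseqs, y in batches:
            pi = model.encode_inputs(pseqs)
            hi = model.encode_inputs(hseqs)
            opt.zero_grad()
            logits, cache = model.forward_pair_batch(pi, hi, with_cache=True)
            loss, dlogits = nn.bce_with_logits(logits, y)
            if math.isnan(loss):
                raise RuntimeError(
                    f"NaN training loss at epoch {epoch}; last batch size "
                    f"{len(y)}, lr={config.learning_rate}")
            model.backward_pair_batch(cache, dlogits)
            opt.step()
            epoch_loss += loss * len(y)
            n_seen += len(y)
        history["train_loss"].append(epoch_loss / n_seen)

        # a run stuck at chance-level BCE (ln 2) after the detection window
        # has lost the initialization lottery; redraw and continue within
        # the same epoch budget
        if (config.plateau_restart_epochs > 0 and config.learning_rate > 0
                and restarts < config.max_restarts
                and epoch + 1 == config.plateau_restart_epochs * (restarts + 1)
                and history["train_loss"][-1] > math.log(2) - 0.005):
            restarts += 1
            logger.info("training loss still at chance after epoch %d; "
                        "re-initializing (restart %d)", epoch, restarts)
            _reinitialize(model, config.seed + 1000 * restarts)
            if config.center_head_init:
                cal_rng = child_rng(config.seed, f"head_init.{restarts}")
                _center_from_batches(model, _draw_epoch_samples(
                    positives, store, host_pool, index, config, cal_rng))
            opt = nn.Adam(model.params(), lr=config.learning_rate)

        if val_batches is not None:
            val_loss, val_auroc = _eval_batches(model, val_batches)
            if math.isnan(val_loss):
                raise RuntimeError(f"NaN validation loss at epoch {epoch}")
            history["val_loss"].append(val_loss)
            history["val_auroc"].append(val_auroc)
            logger.info("epoch %d train_loss=%.5f val_loss=%.5f val_auroc=%.4f",
                        epoch, history["train_loss"][-1], val_loss, val_auroc)
            if best_loss - val_loss > config.early_stop_delta:
                best_loss = val_loss
                best_state = [p.value.copy() for p in model.params()]
                history["best_epoch"] = epoch
                wait = 0
            else:
                wait += 1
                if wait >= config.early_stop_patience:
                    stopped_epoch = epoch + 1
                    break
        else:
            logger.info("epoch %d train_loss=%.5f", epoch,
                        history["train_loss"][-1])

    if best_state is not None:
        for p, v in zip(model.params(), best_state):
            p.value[...] = v
    history["stopped_epoch"] = min(stopped_epoch,
                                   len(history["train_loss"]))
    history["restarts"] = restarts
    return model, history


def grid_search(model_factory, pairs: Sequence[AssociationPair],
                store: GenomeStore, lr_grid: Sequence[float],
                batch_grid: Sequence[int], folds: int = 10,
                base_config: Optional[TrainConfig] = None,
                epochs: int = 5, seed: int = 0) -> TrainConfig:
    """Pick (learning rate, batch size) by k-fold cross-validated loss.

    Each grid cell trains ``folds`` models at a reduced epoch budget; the
    cell with the lowest mean final-fold validation loss wins.  Fold
    assignment is seeded and partitions the pairs exactly once.
    """
    if not lr_grid or not batch_grid:
        raise ValueError("grids must be non-empty")
    base = base_config or TrainConfig()
    positives = [p for p in pairs if p.label == 1]
    rng = child_rng(seed, "grid_search")
    order = rng.permutation(len(positives))
    fold_ids = np.array_split(order, folds)

    best_cfg, best_score = None, math.inf
    for lr in lr_grid:
        for bs in batch_grid:
            cfg = replace(base, learning_rate=lr, batch_size=bs,
                          max_epochs=epochs,
                          early_stop_patience=max(epochs, base.early_stop_patience))
            fold_losses = []
            for f, held in enumerate(fold_ids):
                if len(held) == 0:
                    continue
                held_set = set(held.tolist())
                tr = [positives[i] for i in range(len(positives))
                      if i not in held_set]
                va = [positives[i] for i in sorted(held_set)]
                if not tr:
                    continue
                m = model_factory()
                _, hist = train(m, tr, store, cfg, validation_pairs=va)
                fold_losses.append(hist["val_loss"][-1])
            score = float(np.mean(fold_losses)) if fold_losses else math.inf
            logger.info("grid cell lr=%g batch=%d mean fold loss=%.5f",
                        lr, bs, score)
            if score < best_score:
                best_score, best_cfg = score, replace(base, learning_rate=lr,
                                                      batch_size=bs)
    return best_cfg
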