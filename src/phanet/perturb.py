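"""Sequencing-error and chimeric-contig simulators.

The error model is a single pass over the sequence with per-base total error
probability ``mu + delta``.  Given that an error occurs at a base:

* substitution with probability ``mu / (mu + delta)`` — the base is changed
  to one of the *other* three nucleotides uniformly;
* deletion with probability ``delta / (2 (mu + delta))`` — the base is
  dropped;
* insertion with probability ``delta / (2 (mu + delta))`` — one of A, C, G,
  T (uniform) is inserted immediately after the base.

At most one event happens per original base, so the realized substitution
count is Binomial(L, mu) and insertion/deletion counts are each
Binomial(L, delta/2).

Chimeras model assembly joins: a contiguous segment of ``round(f * L)``
bases at a uniform position is exchanged with an equal-length segment of a
partner contig, preserving both lengths and the combined base multiset.  At
the harness level segments are only swapped between contigs of the same role
(phage with phage, host with host).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Tuple

import numpy as np

from ._rng import child_rng

__all__ = [
    "ErrorProfile",
    "ChimeraSpec",
    "introduce_errors",
    "make_chimera",
    "corrupt_eval_set",
    "PerturbedEvalSet",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class ErrorProfile:
    """Per-base substitution rate ``mu`` and insertion/deletion rate ``delta``."""

    mu: float = 0.0
    delta: float = 0.0

    def __post_init__(self) -> None:
        if self.mu < 0 or self.delta < 0 or self.mu + self.delta > 1:
            raise ValueError("need mu >= 0, delta >= 0 and mu + delta <= 1")


@dataclass(frozen=True)
class ChimeraSpec:
    """Fraction of sequence exchanged and which side(s) of the pair to hit."""

    fraction: float = 0.0
    target: str = "both"  # phage_only | host_only | both

    def __post_init__(self) -> None:
        if not (0.0 <= self.fraction <= 1.0):
            raise ValueError("fraction must be in [0, 1]")
        if self.target not in ("phage_only", "host_only", "both"):
            raise ValueError("target must be phage_only, host_only or both")


def draw_error_events(n_bases: int, profile: ErrorProfile,
                      rng: np.random.Generator) -> np.ndarray:
    """Per-base event codes: 0 none, 1 substitution, 2 deletion, 3 insertion.

    Marginally the counts are Binomial(n, mu), Binomial(n, delta/2) and
    Binomial(n, delta/2) respectively; conditioned on an error occurring the
    split is mu/(mu+delta), delta/(2(mu+delta)), delta/(2(mu+delta)).
    """
    total = profile.mu + profile.delta
    p_indel = profile.delta / 2.0
    return rng.choice(4, size=n_bases,
                      p=[1.0 - total, profile.mu, p_indel, p_indel])


def introduce_errors(sequence: str, profile: ErrorProfile,
                     rng: np.random.Generator) -> str:
    """Apply the single-pass substitution/indel model to a sequence."""
    if profile.mu + profile.delta == 0.0:
        return sequence
    raw = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
    L = raw.size
    events = draw_error_events(L, profile, rng)

    out = raw.copy()
    subs = np.nonzero(events == 1)[0]
    if subs.size:
        # replace by one of the other three bases (uniform); a base outside
        # {A,C,G,T} is replaced by a uniform draw over all four
        cur_idx = np.full(subs.size, 4, dtype=np.int64)
        for b, code in zip(_BASES, range(4)):
            cur_idx[raw[subs] == b] = code
        draw = rng.integers(0, 3, size=subs.size)
        known = cur_idx < 4
        new_idx = np.where(known, (cur_idx + 1 + draw) % 4, draw)
        # for unknown bases draw is in {0,1,2}; widen to all four
        unknown = ~known
        if unknown.any():
            new_idx[unknown] = rng.integers(0, 4, size=int(unknown.sum()))
        out[subs] = _BASES[new_idx]

    inserted = rng.integers(0, 4, size=int((events == 3).sum()))
    keep = events != 2
    # expand: each kept base contributes itself, plus an inserted base after
    # it when its event is insertion
    counts = keep.astype(np.int64) + (events == 3).astype(np.int64)
    total_len = int(counts.sum())
    result = np.empty(total_len, dtype=np.uint8)
    pos = np.cumsum(counts) - counts  # output offset of each original base
    result[pos[keep]] = out[keep]
    ins_positions = pos[events == 3] + 1
    result[ins_positions] = _BASES[inserted]
    return result.tobytes().decode("ascii")


def make_chimera(sequence: str, partner: str, fraction: float,
                 rng: np.random.Generator) -> Tuple[str, str]:
    """Exchange a contiguous segment between two same-role contigs.

    The segment length is ``round(fraction * len(sequence))``; segment start
    positions are uniform in each contig.  Both output lengths equal the
    input lengths and the combined base multiset is conserved.
    """
    seg = int(round(fraction * len(sequence)))
    if seg == 0:
        return sequence, partner
    if seg > len(sequence) or seg > len(partner):
        raise ValueError(
            f"segment of {seg} bases exceeds a contig length "
            f"({len(sequence)}, {len(partner)})")
    i = int(rng.integers(len(sequence) - seg + 1))
    j = int(rng.integers(len(partner) - seg + 1))
    new_seq = sequence[:i] + partner[j:j + seg] + sequence[i + seg:]
    new_partner = partner[:j] + sequence[i:i + seg] + partner[j + seg:]
    return new_seq, new_partner


@dataclass(frozen=True, eq=False)
class PerturbedEvalSet:
    """Sampled contig pairs (with labels) ready for scoring, per repetition."""

    phage_contigs: List[List[str]]   # [repetition][pair]
    host_contigs: List[List[str]]
    labels: np.ndarray               # shared across repetitions
    repetitions: int


def corrupt_eval_set(pairs, store, perturbation=None,
                     phage_length: int = 5000, host_length: int = 5000,
                     repetitions: int = 10, seed: int = 0) -> PerturbedEvalSet:
    """Sample evaluation contig pairs and perturb the designated side(s).

    ``perturbation`` is an :class:`ErrorProfile` (applied to both sides), a
    :class:`ChimeraSpec` (segments exchanged among same-role contigs of the
    evaluation set, on the targeted side only), or None.  The model under
    test is trained error-free; only the evaluation rendering is corrupted.
    Contig lengths default to the fixed 5 kb / 5 kb setting of the
    robustness experiments, averaged over ``repetitions`` draws.
    """
    from .training import build_positives_index, make_negative, sample_contig

    positives = [p for p in pairs if p.label == 1]
    index = build_positives_index(pairs)
    host_pool = sorted({p.host_id for p in pairs} | set(
        h for hs in index.values() for h in hs))
    # separate streams so perturbing one side never shifts the sampling of
    # the other side (or of later repetitions)
    rng = child_rng(seed, "corrupt_eval_set.sample")
    prng = child_rng(seed, "corrupt_eval_set.perturb")

    phage_reps, host_reps = [], []
    labels = None
    for _ in range(repetitions):
        eval_pairs = []
        for p in positives:
            eval_pairs.append(p)
            eval_pairs.append(make_negative(p, host_pool, index, rng))
        pseqs = [sample_contig(store.sample_genome(q.phage_id, rng),
                               phage_length, rng) for q in eval_pairs]
        hseqs = [sample_contig(store.sample_genome(q.host_id, rng),
                               host_length, rng) for q in eval_pairs]
        labels = np.array([q.label for q in eval_pairs], dtype=int)

        if isinstance(perturbation, ErrorProfile):
            pseqs = [introduce_errors(s, perturbation, prng) for s in pseqs]
            hseqs = [introduce_errors(s, perturbation, prng) for s in hseqs]
        elif isinstance(perturbation, ChimeraSpec):
            if perturbation.target in ("phage_only", "both"):
                pseqs = _chimerize_pool(pseqs, perturbation.fraction, prng)
            if perturbation.target in ("host_only", "both"):
                hseqs = _chimerize_pool(hseqs, perturbation.fraction, prng)
        elif perturbation is not None:
            raise TypeError(
                f"unsupported perturbation {type(perturbation).__name__}")
        phage_reps.append(pseqs)
        host_reps.append(hseqs)
    return PerturbedEvalSet(phage_contigs=phage_reps, host_contigs=host_reps,
                            labels=labels, repetitions=repetitions)


def _chimerize_pool(contigs: List[str], fraction: float,
                    rng: np.random.Generator) -> List[str]:
    """Exchange a segment between each contig and a random same-role partner."""
    out = list(contigs)
    if len(out) < 2 or fraction == 0.0:
        return out
    for i in range(len(out)):
        j = int(rng.integers(len(out) - 1))
        if j >= i:
            j += 1
        out[i], out[j] = make_chimera(out[i], out[j], fraction, rng)
    return out
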