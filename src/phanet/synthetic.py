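"""Synthetic phage/host corpus with a planted compositional signal.

The generator emulates the statistical structure that alignment-free
phage-host prediction exploits: genomes of a host *clade* share an order-m
Markov nucleotide composition, and each phage genome mixes its host clade's
composition with a neutral background.  With mixing weight
``signal_strength = s``, every phage base is drawn from
``s * clade_model + (1 - s) * background`` — at ``s = 1`` a phage is
compositionally indistinguishable from its host clade, at ``s = 0`` there is
no phage-host coupling at all and any predictor must sit at chance.

Clade models are rejected and re-drawn until all pairwise total-variation
distances between their stationary base compositions reach a minimum
separation, so "different clade" always means "detectably different
composition".

The corpus writes to exactly the formats the training pipeline consumes:
FASTA genomes, a positive pair TSV, a one-cluster-per-phage cluster map, a
host taxon map (one taxon per host), and a JSON manifest recording the seed
and parameters.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Dict, List, Tuple

import numpy as np
import pandas as pd

from ._rng import child_rng
from .encoding import ContigRecord, Role
from .training import AssociationPair
from .io import read_fasta, read_pair_table, write_fasta, write_pair_table

__all__ = [
    "SyntheticConfig",
    "SyntheticCorpus",
    "sample_clade_composition",
    "stationary_composition",
    "generate_corpus",
    "write_corpus",
    "read_corpus",
    "holdout_split",
]

#: minimum pairwise TV distance between clade stationary compositions
MIN_CLADE_SEPARATION = 0.1


@dataclass(frozen=True)
class SyntheticConfig:
    """Corpus shape and signal parameters.

    Defaults give 5 clades x 4 hosts x 10 phages = 20 hosts and 200 phages,
    with 200 kb host and 40 kb phage genomes.  ``signal_strength`` is the
    mixing weight of the host-clade composition inside phage genomes;
    ``markov_order`` is the context length of the composition models.
    """

    n_host_clades: int = 5
    hosts_per_clade: int = 4
    phages_per_host: int = 10
    host_genome_length: int = 200_000
    phage_genome_length: int = 40_000
    signal_strength: float = 0.8
    markov_order: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.signal_strength <= 1.0):
            raise ValueError("signal_strength must be in [0, 1]")
        if self.markov_order < 0:
            raise ValueError("markov_order must be >= 0")
        for name in ("n_host_clades", "hosts_per_clade", "phages_per_host",
                     "host_genome_length", "phage_genome_length"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")


@dataclass(frozen=True, eq=False)
class SyntheticCorpus:
    """Generated genomes, positive pairs and the generating truth."""

    hosts: List[ContigRecord]
    phages: List[ContigRecord]
    pairs: List[AssociationPair]
    clade_of: Dict[str, str]        # host id -> clade id
    truth: Dict                     # generator parameters for audit


def sample_clade_composition(rng: np.random.Generator,
                             markov_order: int = 2) -> np.ndarray:
    """Draw one order-m Markov transition table over {A, C, G, T}.

    Shape is ``(4**m, 4)`` with rows normalized (order 0 gives a single
    probability 4-vector as a ``(1, 4)`` table).  Rows are Dirichlet draws
    with a mild concentration so compositions are skewed but never
    degenerate.
    """
    if markov_order < 0:
        raise ValueError("markov_order must be >= 0")
    n_states = 4 ** markov_order
    table = rng.dirichlet(np.full(4, 2.0), size=n_states)
    return table


def stationary_composition(table: np.ndarray) -> np.ndarray:
    """Stationary single-base distribution of an order-m transition table."""
    n_states = table.shape[0]
    if n_states == 1:
        return table[0]
    # state = last m bases; appending base b maps state s -> (s*4 + b) mod 4^m
    pi = np.full(n_states, 1.0 / n_states)
    for _ in range(500):
        nxt = np.zeros(n_states)
        flat = (np.arange(n_states)[:, None] * 4 + np.arange(4)[None, :]) % n_states
        np.add.at(nxt, flat.ravel(), (pi[:, None] * table).ravel())
        if np.abs(nxt - pi).sum() < 1e-12:
            pi = nxt
            break
        pi = nxt
    comp = np.zeros(4)
    np.add.at(comp, np.arange(n_states) % 4, pi)
    return comp


def _sample_clade_set(rng: np.random.Generator, n_clades: int,
                      markov_order: int,
                      min_separation: float = MIN_CLADE_SEPARATION,
                      max_tries: int = 10_000) -> List[np.ndarray]:
    """Clade tables with pairwise stationary-composition TV >= min_separation."""
    tables: List[np.ndarray] = []
    comps: List[np.ndarray] = []
    tries = 0
    while len(tables) < n_clades:
        if tries >= max_tries:
            raise RuntimeError(
                f"could not draw {n_clades} clade models separated by "
                f"TV >= {min_separation} in {max_tries} tries")
        tries += 1
        t = sample_clade_composition(rng, markov_order)
        c = stationary_composition(t)
        if all(0.5 * np.abs(c - other).sum() >= min_separation for other in comps):
            tables.append(t)
            comps.append(c)
    return tables


def _sample_markov(table: np.ndarray, length: int,
                   rng: np.random.Generator) -> str:
    """Draw a DNA string from an order-m Markov model (table shape (4^m, 4))."""
    n_states = table.shape[0]
    cum = np.cumsum(table, axis=1)
    cum[:, 3] = 1.0  # guard against rounding
    u = rng.random(length)
    mask = n_states - 1  # 4^m - 1; valid because n_states is a power of 4
    out = np.empty(length, dtype=np.uint8)
    bases = b"ACGT"
    state = int(rng.integers(n_states))
    cum_list = cum.tolist()
    for i in range(length):
        row = cum_list[state]
        r = u[i]
        b = 0 if r < row[0] else 1 if r < row[1] else 2 if r < row[2] else 3
        out[i] = bases[b]
        state = ((state << 2) | b) & mask
    return out.tobytes().decode("ascii")


def generate_corpus(config: SyntheticConfig) -> SyntheticCorpus:
    """Generate hosts, phages and positive pairs under the planted signal.

    Host genomes are drawn from their clade's Markov model.  Each phage is
    assigned one generating host and drawn from the blended table
    ``s * clade + (1 - s) * background`` — the per-base mixture and the
    blended-table draw are the same distribution, so the blend is sampled
    directly.  The background is the uniform i.i.d. model.
    """
    rng = child_rng(config.seed, "synthetic")
    clade_ids = [f"clade{c}" for c in range(config.n_host_clades)]
    tables = _sample_clade_set(rng, config.n_host_clades, config.markov_order)
    background = np.full((4 ** config.markov_order, 4), 0.25)

    hosts: List[ContigRecord] = []
    phages: List[ContigRecord] = []
    pairs: List[AssociationPair] = []
    clade_of: Dict[str, str] = {}

    for c, clade in enumerate(clade_ids):
        for h in range(config.hosts_per_clade):
            host_id = f"host_c{c}_{h}"
            seq = _sample_markov(tables[c], config.host_genome_length, rng)
            hosts.append(ContigRecord(id=host_id, sequence=seq,
                                      role=Role.HOST, source_id=host_id))
            clade_of[host_id] = clade
            blended = (config.signal_strength * tables[c]
                       + (1.0 - config.signal_strength) * background)
            for p in range(config.phages_per_host):
                phage_id = f"phage_c{c}_{h}_{p}"
                pseq = _sample_markov(blended, config.phage_genome_length, rng)
                phages.append(ContigRecord(id=phage_id, sequence=pseq,
                                           role=Role.PHAGE, source_id=phage_id))
                pairs.append(AssociationPair(phage_id, host_id, 1))

    truth = {
        "config": asdict(config),
        "clade_stationary_compositions": {
            clade: stationary_composition(t).tolist()
            for clade, t in zip(clade_ids, tables)
        },
    }
    return SyntheticCorpus(hosts=hosts, phages=phages, pairs=pairs,
                           clade_of=clade_of, truth=truth)


def write_corpus(corpus: SyntheticCorpus, directory) -> Dict[str, Path]:
    """Write the corpus in the formats the training pipeline consumes.

    Emits ``hosts.fasta``, ``phages.fasta``, ``pairs.tsv``, a trivial
    one-cluster-per-phage ``clusters.tsv``, a one-taxon-per-host
    ``host_taxa.tsv`` (plus ``host_clades.tsv`` with the generating clade)
    and ``manifest.json``.  Round-trips losslessly through
    :func:`read_corpus`.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    files = {
        "hosts": directory / "hosts.fasta",
        "phages": directory / "phages.fasta",
        "pairs": directory / "pairs.tsv",
        "clusters": directory / "clusters.tsv",
        "host_taxa": directory / "host_taxa.tsv",
        "host_clades": directory / "host_clades.tsv",
        "manifest": directory / "manifest.json",
    }
    write_fasta(corpus.hosts, files["hosts"])
    write_fasta(corpus.phages, files["phages"])
    write_pair_table(corpus.pairs, files["pairs"])
    pd.DataFrame({"contig_id": [p.id for p in corpus.phages],
                  "cluster_id": [f"cluster_{p.id}" for p in corpus.phages]}
                 ).to_csv(files["clusters"], sep="\t", index=False)
    pd.DataFrame({"host_id": [h.id for h in corpus.hosts],
                  "taxon": [h.id for h in corpus.hosts]}
                 ).to_csv(files["host_taxa"], sep="\t", index=False)
    pd.DataFrame({"host_id": list(corpus.clade_of),
                  "clade": [corpus.clade_of[h] for h in corpus.clade_of]}
                 ).to_csv(files["host_clades"], sep="\t", index=False)
    files["manifest"].write_text(json.dumps(corpus.truth, indent=2) + "\n")
    return files


def read_corpus(directory) -> SyntheticCorpus:
    """Read back a corpus written by :func:`write_corpus`."""
    directory = Path(directory)
    hosts = read_fasta(directory / "hosts.fasta", role=Role.HOST)
    phages = read_fasta(directory / "phages.fasta", role=Role.PHAGE)
    pairs_df = read_pair_table(directory / "pairs.tsv")
    pairs = [AssociationPair(r.phage_id, r.host_id, int(r.label))
             for r in pairs_df.itertuples()]
    clades = pd.read_csv(directory / "host_clades.tsv", sep="\t", dtype=str)
    clade_of = dict(zip(clades["host_id"], clades["clade"]))
    truth = json.loads((directory / "manifest.json").read_text())
    return SyntheticCorpus(hosts=hosts, phages=phages, pairs=pairs,
                           clade_of=clade_of, truth=truth)


def holdout_split(corpus: SyntheticCorpus, holdout_fraction: float = 0.2,
                  seed: int = 0, unseen_clades: bool = False,
                  ) -> Tuple[List[AssociationPair], List[AssociationPair]]:
    """Split positive pairs for held-out evaluation.

    Default: hold out unseen *phages* of seen clades (within-distribution
    generalization).  With ``unseen_clades=True``, entire clades are held
    out instead — the harder out-of-distribution task.
    """
    rng = child_rng(seed, "holdout_split")
    if unseen_clades:
        clades = sorted(set(corpus.clade_of.values()))
        n_hold = max(1, int(round(holdout_fraction * len(clades))))
        held = set(c for c in
                   np.array(clades)[rng.permutation(len(clades))[:n_hold]])
        held_hosts = {h for h, c in corpus.clade_of.items() if c in held}
        train = [p for p in corpus.pairs if p.host_id not in held_hosts]
        test = [p for p in corpus.pairs if p.host_id in held_hosts]
    else:
        phage_ids = sorted({p.phage_id for p in corpus.pairs})
        n_hold = max(1, int(round(holdout_fraction * len(phage_ids))))
        held = set(np.array(phage_ids)[rng.permutation(len(phage_ids))[:n_hold]])
        train = [p for p in corpus.pairs if p.phage_id not in held]
        test = [p for p in corpus.pairs if p.phage_id in held]
    return train, test
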