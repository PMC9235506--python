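"""Synthetic corpus generator: planted signal, separation, round-trips."""

import numpy as np
import pytest
from scipy import stats

from phanet.evaluation import evaluate_length_grid, kmer_baseline_score
from phanet.synthetic import (
    SyntheticConfig,
    generate_corpus,
    holdout_split,
    read_corpus,
    sample_clade_composition,
    write_corpus,
)
from phanet.training import GenomeStore


SMALL = dict(n_host_clades=3, hosts_per_clade=2, phages_per_host=2,
             host_genome_length=30_000, phage_genome_length=15_000)


class TestCladeComposition:
    def test_order_zero_is_single_normalized_row(self):
        table = sample_clade_composition(np.random.default_rng(0), markov_order=0)
        assert table.shape == (1, 4)
        assert table.sum() == pytest.approx(1.0)

    def test_order_two_rows_normalized(self):
        table = sample_clade_composition(np.random.default_rng(1), markov_order=2)
        assert table.shape == (16, 4)
        assert np.allclose(table.sum(axis=1), 1.0)

    def test_clades_separated_in_stationary_composition(self):
        corpus = generate_corpus(SyntheticConfig(**SMALL, seed=2))
        comps = [np.array(c) for c in
                 corpus.truth["clade_stationary_compositions"].values()]
        for i in range(len(comps)):
            for j in range(i + 1, len(comps)):
                tv = 0.5 * np.abs(comps[i] - comps[j]).sum()
                assert tv >= 0.1

    def test_fixed_seed_gives_identical_tables(self):
        a = sample_clade_composition(np.random.default_rng(3), 1)
        b = sample_clade_composition(np.random.default_rng(3), 1)
        assert np.array_equal(a, b)


class TestGenerateCorpus:
    def test_default_counts(self):
        cfg = SyntheticConfig()
        assert cfg.n_host_clades * cfg.hosts_per_clade == 20
        corpus = generate_corpus(SyntheticConfig(**SMALL, seed=4))
        assert len(corpus.hosts) == 6
        assert len(corpus.phages) == 12
        assert len(corpus.pairs) == 12
        assert all(p.label == 1 for p in corpus.pairs)

    def test_every_phage_has_exactly_one_host_and_unique_ids(self):
        corpus = generate_corpus(SyntheticConfig(**SMALL, seed=5))
        phage_ids = [p.phage_id for p in corpus.pairs]
        assert len(phage_ids) == len(set(phage_ids))
        all_ids = [r.id for r in corpus.hosts + corpus.phages]
        assert len(all_ids) == len(set(all_ids))

    def test_reproducible_under_seed(self):
        a = generate_corpus(SyntheticConfig(**SMALL, seed=6))
        b = generate_corpus(SyntheticConfig(**SMALL, seed=6))
        assert [r.sequence for r in a.hosts] == [r.sequence for r in b.hosts]
        assert [r.sequence for r in a.phages] == [r.sequence for r in b.phages]

    def test_full_signal_matches_host_clade_composition(self):
        """At signal 1 a phage's 3-mer usage is indistinguishable from its
        host clade's (chi-square on 3-mer counts)."""
        cfg = SyntheticConfig(n_host_clades=2, hosts_per_clade=1,
                              phages_per_host=1, host_genome_length=60_000,
                              phage_genome_length=60_000,
                              signal_strength=1.0, markov_order=1, seed=7)
        corpus = generate_corpus(cfg)
        for c in range(2):
            host = next(r for r in corpus.hosts if r.id == f"host_c{c}_0")
            phage = next(r for r in corpus.phages
                         if r.id == f"phage_c{c}_0_0")
            h = _kmer_counts(host.sequence, 3)
            p = _kmer_counts(phage.sequence, 3)
            keep = (h + p) > 10
            _, pval, _, _ = stats.chi2_contingency(np.vstack([h[keep], p[keep]]))
            assert pval > 0.01

    def test_no_signal_gives_chance_level_baseline(self):
        cfg = SyntheticConfig(n_host_clades=4, hosts_per_clade=2,
                              phages_per_host=5, host_genome_length=30_000,
                              phage_genome_length=15_000,
                              signal_strength=0.0, seed=8)
        corpus = generate_corpus(cfg)
        store = GenomeStore.from_records(corpus.hosts + corpus.phages)
        result = evaluate_length_grid(
            None, corpus.pairs, store, [2000], [2000], k=5, seed=8,
            scorer=lambda p, h: -kmer_baseline_score(p, h, k=3))
        assert abs(result.auroc[0, 0] - 0.5) < 0.05

    def test_signal_monotonicity_of_baseline_auroc(self):
        """Compositional signal strength orders the baseline's AUROC."""
        aurocs = []
        for s in (0.0, 0.4, 0.8):
            cfg = SyntheticConfig(n_host_clades=4, hosts_per_clade=2,
                                  phages_per_host=5,
                                  host_genome_length=30_000,
                                  phage_genome_length=15_000,
                                  signal_strength=s, seed=9)
            corpus = generate_corpus(cfg)
            store = GenomeStore.from_records(corpus.hosts + corpus.phages)
            r = evaluate_length_grid(
                None, corpus.pairs, store, [2000], [2000], k=5, seed=9,
                scorer=lambda p, h: -kmer_baseline_score(p, h, k=3))
            aurocs.append(r.auroc[0, 0])
        assert aurocs[0] < aurocs[1] + 0.05
        assert aurocs[1] < aurocs[2] + 0.05
        assert aurocs[2] > aurocs[0]


class TestCorpusIO:
    def test_write_read_roundtrip(self, tmp_path, tiny_corpus):
        write_corpus(tiny_corpus, tmp_path)
        back = read_corpus(tmp_path)
        assert [r.sequence for r in back.hosts] == \
            [r.sequence for r in tiny_corpus.hosts]
        assert [r.sequence for r in back.phages] == \
            [r.sequence for r in tiny_corpus.phages]
        assert back.pairs == tiny_corpus.pairs
        assert back.clade_of == tiny_corpus.clade_of

    def test_headers_match_pair_table(self, tmp_path, tiny_corpus):
        files = write_corpus(tiny_corpus, tmp_path)
        import pandas as pd
        pairs = pd.read_csv(files["pairs"], sep="\t")
        phage_ids = {r.id for r in tiny_corpus.phages}
        host_ids = {r.id for r in tiny_corpus.hosts}
        assert set(pairs["phage_id"]) <= phage_ids
        assert set(pairs["host_id"]) <= host_ids

    def test_cluster_map_covers_all_phages(self, tmp_path, tiny_corpus):
        files = write_corpus(tiny_corpus, tmp_path)
        import pandas as pd
        clusters = pd.read_csv(files["clusters"], sep="\t")
        assert set(clusters["contig_id"]) == {r.id for r in tiny_corpus.phages}


class TestHoldoutSplit:
    def test_unseen_phage_split_partitions_pairs(self, tiny_corpus):
        tr, te = holdout_split(tiny_corpus, 0.25, seed=0)
        assert len(tr) + len(te) == len(tiny_corpus.pairs)
        assert not ({p.phage_id for p in tr} & {p.phage_id for p in te})

    def test_unseen_clade_split_separates_hosts(self, tiny_corpus):
        tr, te = holdout_split(tiny_corpus, 0.34, seed=0, unseen_clades=True)
        tr_clades = {tiny_corpus.clade_of[p.host_id] for p in tr}
        te_clades = {tiny_corpus.clade_of[p.host_id] for p in te}
        assert te_clades and not (tr_clades & te_clades)


def _kmer_counts(sequence: str, k: int) -> np.ndarray:
    """Non-overlapping k-mer counts (overlap would correlate the cells)."""
    from phanet.encoding import _codes

    codes = _codes(sequence)
    n = len(codes) // k
    tri = codes[: n * k].reshape(n, k).astype(np.int64)
    idx = np.zeros(n, dtype=np.int64)
    for j in range(k):
        idx = idx * 4 + tri[:, j]
    return np.bincount(idx, minlength=4 ** k)
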