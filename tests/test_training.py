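"""Split hygiene, contig sampling, negative construction and the training loop."""

import numpy as np
import pytest
from scipy import stats

from phanet.model import AssociationModel, ModelConfig
from phanet.training import (
    AssociationPair,
    GenomeStore,
    SplitSpec,
    TrainConfig,
    build_positives_index,
    grid_search,
    make_negative,
    sample_contig,
    split_pairs,
    train,
    _draw_epoch_samples,
)
from phanet._rng import child_rng
from phanet.synthetic import holdout_split

from conftest import random_dna


class TestSplitPairs:
    def _taxa(self, pairs):
        return {p.host_id: p.host_id for p in pairs}

    def test_shared_cluster_pairs_end_up_together_in_validation(self):
        # two pairs in one cluster plus enough singletons that the random
        # 80/20 draw separates the clustered pair across sets
        pairs = [AssociationPair("pA", "h1"), AssociationPair("pB", "h2")]
        pairs += [AssociationPair(f"p{i}", f"h{i + 3}") for i in range(8)]
        clusters = {"pA": "c0", "pB": "c0"}
        clusters.update({f"p{i}": f"c{i + 1}" for i in range(8)})
        for seed in range(10):
            tr, va = split_pairs(pairs, SplitSpec(cluster_of=clusters, seed=seed),
                                 self._taxa(pairs))
            tr_clusters = {clusters[p.phage_id] for p in tr}
            va_clusters = {clusters[p.phage_id] for p in va}
            assert not (tr_clusters & va_clusters)
            # the c0 cluster is represented by a single phage after dedup
            c0 = [p for p in tr + va if clusters[p.phage_id] == "c0"]
            assert len({p.phage_id for p in c0}) == 1

    def test_all_pairs_one_cluster_degenerates_to_validation(self):
        pairs = [AssociationPair(f"p{i}", f"h{i}") for i in range(5)]
        clusters = {f"p{i}": "c0" for i in range(5)}
        tr, va = split_pairs(pairs, SplitSpec(cluster_of=clusters, seed=0),
                             self._taxa(pairs))
        assert tr == []
        assert len(va) >= 1

    def test_split_is_deterministic_under_seed(self):
        pairs = [AssociationPair(f"p{i}", f"h{i % 7}") for i in range(100)]
        clusters = {f"p{i}": f"c{i}" for i in range(100)}
        spec = SplitSpec(cluster_of=clusters, seed=42)
        taxa = self._taxa(pairs)
        assert split_pairs(pairs, spec, taxa) == split_pairs(pairs, spec, taxa)

    def test_no_taxon_leakage_with_shared_hosts(self):
        pairs = [AssociationPair(f"p{i}", f"h{i % 5}") for i in range(50)]
        clusters = {f"p{i}": f"c{i}" for i in range(50)}
        taxa = {f"h{i}": f"taxon{i % 2}" for i in range(5)}
        tr, va = split_pairs(pairs, SplitSpec(cluster_of=clusters, seed=3), taxa)
        assert not ({taxa[p.host_id] for p in tr} & {taxa[p.host_id] for p in va})

    def test_missing_cluster_entries_reported(self):
        pairs = [AssociationPair("pX", "h1")]
        with pytest.raises(ValueError, match="pX"):
            split_pairs(pairs, SplitSpec(cluster_of={}, seed=0), {"h1": "h1"})

    def test_missing_taxon_entries_reported(self):
        pairs = [AssociationPair("pX", "h1")]
        with pytest.raises(ValueError, match="h1"):
            split_pairs(pairs, SplitSpec(cluster_of={"pX": "c0"}, seed=0), {})


class TestSampleContig:
    def test_substring_of_requested_length(self):
        rng = np.random.default_rng(0)
        genome = random_dna(rng, 10_000)
        for _ in range(20):
            contig = sample_contig(genome, 200, rng)
            assert len(contig) == 200
            assert contig in genome

    def test_short_genome_returned_whole(self):
        rng = np.random.default_rng(0)
        genome = random_dna(rng, 150)
        assert sample_contig(genome, 200, rng) == genome

    def test_seeded_determinism(self):
        genome = random_dna(np.random.default_rng(1), 5_000)
        a = sample_contig(genome, 300, np.random.default_rng(7))
        b = sample_contig(genome, 300, np.random.default_rng(7))
        assert a == b

    def test_empty_genome_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            sample_contig("", 100, np.random.default_rng(0))


class TestMakeNegative:
    def test_negative_host_uniform_over_non_positives(self):
        hosts = [f"h{i}" for i in range(10)]
        pos = AssociationPair("p0", "h0")
        index = {"p0": {"h0"}}
        rng = np.random.default_rng(0)
        draws = [make_negative(pos, hosts, index, rng).host_id
                 for _ in range(10_000)]
        counts = [draws.count(h) for h in hosts]
        assert counts[0] == 0
        chi2 = stats.chisquare(counts[1:])
        assert chi2.pvalue > 1e-4  # uniform over the other nine

    def test_negative_never_collides_with_positives(self):
        hosts = [f"h{i}" for i in range(5)]
        index = {"p0": {"h0", "h2", "h4"}}
        rng = np.random.default_rng(1)
        for _ in range(200):
            neg = make_negative(AssociationPair("p0", "h0"), hosts, index, rng)
            assert neg.label == 0
            assert neg.host_id not in index["p0"]

    def test_phage_paired_with_all_hosts_rejected(self):
        hosts = ["h0", "h1"]
        index = {"p0": {"h0", "h1"}}
        with pytest.raises(ValueError, match="every host"):
            make_negative(AssociationPair("p0", "h0"), hosts, index,
                          np.random.default_rng(0))


class TestEpochSampling:
    def test_one_to_one_negative_ratio_per_epoch(self, tiny_corpus, tiny_store):
        positives = tiny_corpus.pairs
        index = build_positives_index(positives)
        cfg = TrainConfig.desk_scale(seed=0)
        batches = _draw_epoch_samples(positives, tiny_store,
                                      sorted({p.host_id for p in positives}),
                                      index, cfg, child_rng(0, "t"))
        labels = np.concatenate([b[2] for b in batches])
        assert labels.sum() == len(positives)
        assert len(labels) == 2 * len(positives)

    def test_consecutive_epochs_draw_distinct_contigs(self, tiny_corpus, tiny_store):
        positives = tiny_corpus.pairs
        index = build_positives_index(positives)
        cfg = TrainConfig.desk_scale(seed=0)
        hosts = sorted({p.host_id for p in positives})
        rng = child_rng(0, "t")
        e1 = _draw_epoch_samples(positives, tiny_store, hosts, index, cfg, rng)
        e2 = _draw_epoch_samples(positives, tiny_store, hosts, index, cfg, rng)
        assert [b[0] for b in e1] != [b[0] for b in e2]

    def test_batch_shares_one_length_per_role(self, tiny_corpus, tiny_store):
        positives = tiny_corpus.pairs
        index = build_positives_index(positives)
        cfg = TrainConfig.desk_scale(seed=0)
        batches = _draw_epoch_samples(positives, tiny_store,
                                      sorted({p.host_id for p in positives}),
                                      index, cfg, child_rng(1, "t"))
        for pseqs, hseqs, _ in batches:
            assert len({len(s) for s in pseqs}) == 1
            assert len({len(s) for s in hseqs}) == 1


class TestTrain:
    def _pairs(self, corpus):
        return holdout_split(corpus, 0.25, seed=0)

    def test_zero_learning_rate_leaves_parameters_unchanged(self, tiny_corpus,
                                                            tiny_store):
        tr, va = self._pairs(tiny_corpus)
        model = AssociationModel(ModelConfig.desk_scale(seed=0))
        cfg = TrainConfig.desk_scale(learning_rate=0.0, max_epochs=1,
                                     center_head_init=False, seed=0)
        before = [p.value.copy() for p in model.params()]
        model, _ = train(model, tr, tiny_store, cfg, validation_pairs=va)
        for b, p in zip(before, model.params()):
            assert np.array_equal(b, p.value)

    def test_identical_seeds_give_identical_history(self, tiny_corpus, tiny_store):
        tr, va = self._pairs(tiny_corpus)
        histories = []
        for _ in range(2):
            model = AssociationModel(ModelConfig.desk_scale(seed=4))
            _, hist = train(model, tr, tiny_store,
                            TrainConfig.desk_scale(max_epochs=2, seed=4),
                            validation_pairs=va)
            histories.append((hist["train_loss"], hist["val_loss"]))
        assert histories[0] == histories[1]

    def test_early_stopping_fires_on_plateau(self, tiny_corpus, tiny_store):
        # zero learning rate makes the validation loss exactly constant
        tr, va = self._pairs(tiny_corpus)
        model = AssociationModel(ModelConfig.desk_scale(seed=5))
        cfg = TrainConfig.desk_scale(learning_rate=0.0, max_epochs=30,
                                     early_stop_patience=3,
                                     center_head_init=False, seed=5)
        _, hist = train(model, tr, tiny_store, cfg, validation_pairs=va)
        assert hist["stopped_epoch"] <= cfg.early_stop_patience + 1

    def test_training_reduces_loss_on_planted_signal(self, trained_desk_model):
        _, _, _, hist = trained_desk_model
        assert hist["train_loss"][-1] < hist["train_loss"][0]
        assert hist["val_auroc"][-1] > hist["val_auroc"][0]

    def test_no_positive_pairs_rejected(self, tiny_store):
        model = AssociationModel(ModelConfig.desk_scale(seed=0))
        with pytest.raises(ValueError, match="positive"):
            train(model, [AssociationPair("p", "h", 0)], tiny_store,
                  TrainConfig.desk_scale(seed=0))


class TestGridSearch:
    def test_single_cell_grid_returns_that_cell(self, tiny_corpus, tiny_store):
        cfg = grid_search(
            lambda: AssociationModel(ModelConfig.desk_scale(seed=0)),
            tiny_corpus.pairs, tiny_store, lr_grid=[0.004], batch_grid=[8],
            folds=2, base_config=TrainConfig.desk_scale(seed=0), epochs=1)
        assert cfg.learning_rate == 0.004
        assert cfg.batch_size == 8

    def test_fold_partition_covers_pairs_exactly_once(self):
        positives = [AssociationPair(f"p{i}", f"h{i % 3}") for i in range(17)]
        rng = child_rng(0, "grid_search")
        order = rng.permutation(len(positives))
        folds = np.array_split(order, 5)
        seen = np.concatenate(folds)
        assert sorted(seen.tolist()) == list(range(17))


class TestGenomeStore:
    def test_multiple_assemblies_sampled_uniformly(self):
        store = GenomeStore()
        store.add("h", "AAAA")
        store.add("h", "CCCC")
        rng = np.random.default_rng(0)
        draws = {store.sample_genome("h", rng) for _ in range(50)}
        assert draws == {"AAAA", "CCCC"}

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            GenomeStore().add("x", "")
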