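"""Model behavior: loss analytics, invariances, pairing, training."""

import math

import numpy as np
import pytest

from retroranker import (
    EncoderConfig,
    RankerModel,
    ReactionRecord,
    SchemaError,
    SynthConfig,
    TrainConfig,
    UsageError,
    annotate_changes,
    build_reaction_graphs,
    encode_reaction,
    featurize_record,
    generate_dataset,
    load_checkpoint,
    make_training_pairs,
    pairwise_loss,
    parse_mapped_reaction,
    save_checkpoint,
    score_candidate,
    train,
)
from retroranker.featurization import ATOM_DIM, GraphData
from retroranker.ranker import UNSCORABLE_SCORE, score_predictions
from conftest import ESTERIFICATION, permute_atoms


@pytest.fixture(scope="module")
def tiny_model():
    return RankerModel(EncoderConfig(hidden_width=16, num_layers=2), seed=4)


class TestPairwiseLoss:
    @pytest.mark.parametrize("eps", [0.0, 0.1, 0.3])
    def test_equal_scores_give_ln2(self, eps):
        assert pairwise_loss(0.7, 0.7, eps) == pytest.approx(math.log(2), abs=1e-12)

    def test_vanishes_in_the_large_margin_limit_without_smoothing(self):
        assert pairwise_loss(60.0, 0.0, 0.0) == pytest.approx(0.0, abs=1e-12)

    def test_strictly_decreasing_in_margin(self):
        # without smoothing the loss decreases over the whole margin axis
        margins = np.linspace(-10, 10, 100)
        losses = [pairwise_loss(m, 0.0, 0.0) for m in margins]
        assert all(a > b for a, b in zip(losses, losses[1:]))
        # with smoothing epsilon the minimum sits at margin ln((1-eps)/eps);
        # the loss is strictly decreasing up to that point
        eps = 0.1
        bound = math.log((1 - eps) / eps)
        margins = np.linspace(-10, bound, 100)
        losses = [pairwise_loss(m, 0.0, eps) for m in margins]
        assert all(a > b for a, b in zip(losses, losses[1:]))

    def test_symmetric_sum_convexity_bound(self):
        rng = np.random.default_rng(0)
        for s1, s2 in rng.normal(scale=3, size=(200, 2)):
            total = pairwise_loss(s1, s2, 0.1) + pairwise_loss(s2, s1, 0.1)
            assert total >= 2 * math.log(2) - 1e-12
            if abs(s1 - s2) > 1e-6:
                assert total > 2 * math.log(2)

    def test_epsilon_out_of_range(self):
        with pytest.raises(UsageError):
            pairwise_loss(1.0, 0.0, 0.5)


class TestEncoderAndScorer:
    def test_embedding_length_and_determinism(self, tiny_model, fixture_records):
        graphs = featurize_record(fixture_records["esterification"])
        emb = encode_reaction(tiny_model, graphs)
        assert emb.shape == (2 * tiny_model.config.hidden_width,)
        assert score_candidate(tiny_model, graphs) == score_candidate(tiny_model, graphs)

    def test_permutation_invariance(self, tiny_model):
        rng = np.random.default_rng(9)
        record = parse_mapped_reaction(ESTERIFICATION)
        graphs = featurize_record(record)
        base_emb = encode_reaction(tiny_model, graphs)
        base_score = score_candidate(tiny_model, graphs)
        for _ in range(5):
            permuted = ReactionRecord(
                product=permute_atoms(record.product, rng),
                reactants=[permute_atoms(r, rng) for r in record.reactants],
            )
            g = featurize_record(permuted)
            np.testing.assert_allclose(encode_reaction(tiny_model, g), base_emb, atol=1e-5)
            assert abs(score_candidate(tiny_model, g) - base_score) < 1e-5

    def test_degenerate_single_atom_graph_is_finite(self, tiny_model):
        g = GraphData(
            node_features=np.zeros((1, ATOM_DIM)),
            edge_features=np.zeros((0, 7)),
            edges=np.zeros((0, 2), dtype=np.int64),
        )
        from retroranker.featurization import FeaturizedReactionGraph

        graphs = FeaturizedReactionGraph(reactant_graph=g, product_graph=g)
        emb = encode_reaction(tiny_model, graphs)
        assert np.all(np.isfinite(emb))
        assert math.isfinite(score_candidate(tiny_model, graphs))

    def test_schema_mismatch_rejected(self, tiny_model, fixture_records):
        graphs = featurize_record(fixture_records["identity"])
        graphs.schema_hash = "0" * 16
        with pytest.raises(SchemaError):
            score_candidate(tiny_model, graphs)


class TestMakeTrainingPairs:
    def test_exhaustive_when_budget_allows(self, small_dataset):
        lists, _ = small_dataset
        pairs = make_training_pairs(lists[:1], max_pairs=9, seed=0)
        assert len(pairs) == 9
        assert all(pos.is_recorded and not neg.is_recorded for pos, neg in pairs)

    def test_list_without_recorded_contributes_nothing(self, small_dataset):
        lists, _ = small_dataset
        clone = lists[0]
        stripped = type(clone)(
            product_smiles=clone.product_smiles,
            candidates=[
                type(c)(
                    product=c.product, reactants=c.reactants,
                    original_rank=c.original_rank, is_recorded=False,
                )
                for c in clone.candidates
            ],
        )
        assert make_training_pairs([stripped], max_pairs=3, seed=0) == []

    def test_seeded_sampling_reproducible(self, small_dataset):
        lists, _ = small_dataset
        a = make_training_pairs(lists, max_pairs=3, seed=5)
        b = make_training_pairs(lists, max_pairs=3, seed=5)
        assert [(id(p), id(n)) for p, n in a] == [(id(p), id(n)) for p, n in b]


class TestTraining:
    def test_zero_epochs_returns_initialized_model(self, small_dataset):
        lists, _ = small_dataset
        config = EncoderConfig(hidden_width=8, num_layers=1)
        fresh = RankerModel(config, seed=3)
        reference = {k: v.copy() for k, v in fresh.state_dict().items()}
        trained, log = train(
            lists[:10], fresh, TrainConfig(epochs=0, seed=3, validation_fraction=0.0)
        )
        for k, v in trained.state_dict().items():
            np.testing.assert_array_equal(v, reference[k])
        assert log.epoch_losses == []

    def test_learns_separable_synthetic_data(self, separable_config):
        lists, _ = generate_dataset(separable_config)
        model, log = train(
            lists,
            EncoderConfig(hidden_width=32, num_layers=2),
            TrainConfig(epochs=4, seed=0, max_pairs_per_product=3),
        )
        assert log.best_val_accuracy > 0.9

    def test_same_seed_reproduces_training(self, separable_config):
        import dataclasses

        cfg = dataclasses.replace(separable_config, n_products=30)
        losses = []
        for _ in range(2):
            lists, _ = generate_dataset(cfg)
            _model, log = train(
                lists,
                EncoderConfig(hidden_width=8, num_layers=1),
                TrainConfig(epochs=2, seed=1, max_pairs_per_product=2),
            )
            losses.append(log.epoch_losses)
        np.testing.assert_allclose(losses[0], losses[1], rtol=1e-12)


class TestScoringAndCheckpoints:
    def test_unscorable_candidate_gets_minimum_score(self, tiny_model, tmp_path):
        from retroranker import read_predictions

        line = (
            '{"product": "[CH3:1][OH:2]", "recorded": null, "candidates": ['
            '{"rank": 1, "reactants": "[CH3:1][OH:2]", "score": null},'
            '{"rank": 2, "reactants": "C1CC", "score": null}]}'
        )
        p = tmp_path / "u.jsonl"
        p.write_text(line + "\n")
        lists = read_predictions(p)
        scores = score_predictions(tiny_model, lists)
        assert scores[0][1] == UNSCORABLE_SCORE
        assert np.isfinite(scores[0][0])

    def test_checkpoint_round_trip(self, tiny_model, tmp_path, fixture_records):
        path = str(tmp_path / "model.ckpt")
        save_checkpoint(tiny_model, path)
        back = load_checkpoint(path)
        graphs = featurize_record(fixture_records["esterification"])
        assert score_candidate(back, graphs) == pytest.approx(
            score_candidate(tiny_model, graphs), abs=1e-12
        )
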