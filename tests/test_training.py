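"""Learning-rate schedules, phase alternation, freeze masks, early
stopping and the two training stages."""

import math

import numpy as np
import pytest

import targen as tg
from targen.training import (Adam, FinetuneConfig, PretrainConfig,
                             apply_freeze_mask, early_stop, evaluate_loss,
                             finetune_lr, phase_for_epoch, pretrain_lr)


class TestPretrainSchedule:
    def test_reference_values(self):
        cfg = PretrainConfig()
        assert pretrain_lr(1, cfg) == 1e-4
        assert pretrain_lr(2, cfg) == pytest.approx(9.5e-5)

    def test_strictly_decreasing(self):
        cfg = PretrainConfig()
        lrs = [pretrain_lr(e, cfg) for e in range(1, 101)]
        assert all(b < a for a, b in zip(lrs, lrs[1:]))

    def test_epoch_must_be_one_based(self):
        with pytest.raises(ValueError):
            pretrain_lr(0, PretrainConfig())


class TestFinetuneSchedule:
    cfg = FinetuneConfig()

    def test_anchors(self):
        assert finetune_lr(0, self.cfg) == 0.0
        assert finetune_lr(20, self.cfg) == pytest.approx(1e-3)
        assert finetune_lr(100, self.cfg) == 0.0

    def test_cycle_periodicity(self):
        for e in (0, 5, 20, 60, 99):
            assert finetune_lr(e + 100, self.cfg) == \
                pytest.approx(finetune_lr(e, self.cfg))

    def test_epoch_sixty_closed_form(self):
        expected = 1e-3 * (1 + math.cos(math.pi * 40 / 80)) / 2
        assert finetune_lr(60, self.cfg) == pytest.approx(expected)

    def test_out_of_budget_epoch_rejected(self):
        with pytest.raises(ValueError):
            finetune_lr(200, self.cfg)
        with pytest.raises(ValueError):
            finetune_lr(-1, self.cfg)

    def test_cycle_budget_invariant(self):
        with pytest.raises(ValueError):
            FinetuneConfig(cycle_len=100, n_cycles=2, max_epochs=150)


class TestPhaseAlternation:
    cfg = FinetuneConfig()

    @pytest.mark.parametrize("epoch, phase", [
        (0, "adapter"), (14, "adapter"), (15, "main"), (24, "main"),
        (25, "adapter"), (39, "adapter"), (40, "main"), (50, "adapter"),
    ])
    def test_fifteen_ten_pattern_with_period_twenty_five(self, epoch, phase):
        assert phase_for_epoch(epoch, self.cfg) == phase

    def test_mask_by_phase(self):
        groups = {"embeddings": [], "target_table": [], "output_linear": [],
                  "block0.self_attn": [], "block1.ffn": [],
                  "block1.adapter": [], "block2.cond_attn": []}
        adapter = apply_freeze_mask(groups, "adapter")
        assert adapter["block1.adapter"]
        assert adapter["embeddings"] and adapter["output_linear"] \
            and adapter["target_table"]
        assert not adapter["block0.self_attn"] and not adapter["block1.ffn"] \
            and not adapter["block2.cond_attn"]
        main = apply_freeze_mask(groups, "main")
        assert not main["block1.adapter"]
        assert all(main[g] for g in groups if g != "block1.adapter")
        with pytest.raises(ValueError):
            apply_freeze_mask(groups, "warmup")


class TestEarlyStop:
    def test_plateau_stops_at_patience(self):
        history = [3, 2, 2, 2, 2, 2, 2]
        assert not early_stop(history[:-1], patience=5)
        assert early_stop(history, patience=5)

    def test_strict_descent_never_stops(self):
        history = list(range(200, 0, -1))
        for k in range(1, len(history) + 1):
            assert not early_stop(history[:k], patience=5)

    def test_improvement_resets_the_counter(self):
        assert not early_stop([5, 4, 6, 6, 6, 6, 3, 4, 4], patience=5)


def _finetune_fixture(pretrained_tiny, clone, target_sets, vocab300,
                      max_epochs=2, seed=3):
    model = clone(pretrained_tiny)
    tr = target_sets.records[target_sets.records["split"] == "train"]
    va = target_sets.records[target_sets.records["split"] == "valid"]
    cfg = FinetuneConfig(adapter_phase_len=15, main_phase_len=10,
                         max_epochs=max_epochs, cycle_len=max_epochs,
                         n_cycles=1, warmup_epochs=max(1, max_epochs - 1),
                         peak_lr=3e-3, batch_size=64, patience=5)
    return model, tr, va, cfg


class TestFreezeDuringTraining:
    def _one_phase_epoch(self, pretrained_tiny, clone, target_sets,
                         vocab300, phase):
        from targen.training import _run_epoch
        model, tr, va, _ = _finetune_fixture(pretrained_tiny, clone,
                                             target_sets, vocab300)
        model.add_adapters((1, 2), seed=0)
        from targen.training import encode_dataset
        tokens, targets, _ = encode_dataset(tr, vocab300, model.config.max_len)
        groups = model.parameter_groups()
        gmask = apply_freeze_mask(groups, phase)
        trainable = {n: gmask[g] for g, names in groups.items() for n in names}
        before = model.state_dict()
        rng = np.random.default_rng(0)
        _run_epoch(model, tokens, targets, 64, 1e-3, Adam(model.params),
                   rng, trainable)
        return model, before, groups, trainable

    def test_adapter_phase_freezes_attention_and_ffn(
            self, pretrained_tiny, clone, target_sets, vocab300):
        model, before, groups, trainable = self._one_phase_epoch(
            pretrained_tiny, clone, target_sets, vocab300, "adapter")
        for g, names in groups.items():
            for n in names:
                same = np.array_equal(model.params[n].data, before[n])
                if not trainable[n]:
                    assert same, f"frozen {n} moved in adapter phase"
        # always-trained layers and adapters actually move
        assert not np.array_equal(model.params["tok_emb"].data, before["tok_emb"])
        assert not np.array_equal(model.params["out.W"].data, before["out.W"])
        assert not np.array_equal(model.params["block1.adapter.W_down"].data,
                                  before["block1.adapter.W_down"])

    def test_main_phase_keeps_adapters_bit_identical(
            self, pretrained_tiny, clone, target_sets, vocab300):
        model, before, groups, trainable = self._one_phase_epoch(
            pretrained_tiny, clone, target_sets, vocab300, "main")
        for b in (1, 2):
            for suffix in ("W_down", "W_up"):
                n = f"block{b}.adapter.{suffix}"
                assert np.array_equal(model.params[n].data, before[n])
        assert not np.array_equal(model.params["block0.self_attn.W_q"].data,
                                  before["block0.self_attn.W_q"])

    def test_null_target_row_stays_pinned_to_zero(
            self, pretrained_tiny, clone, target_sets, vocab300):
        model, before, *_ = self._one_phase_epoch(
            pretrained_tiny, clone, target_sets, vocab300, "adapter")
        assert np.all(model.params["target_table"].data[0] == 0.0)
        assert not np.array_equal(model.params["target_table"].data[1:],
                                  before["target_table"][1:])


class TestPretrainLoop:
    def test_two_epoch_loss_decreases(self, corpus300, vocab300):
        cfg = tg.ModelConfig(vocab_size=len(vocab300), d_model=32, n_heads=2,
                             n_blocks=3, adapter_dim=8, max_len=48, dropout=0.1)
        model = tg.ConditionalDecoder(cfg, seed=0)
        sub = corpus300.records.head(200)
        history = tg.pretrain(model, sub, vocab300,
                              PretrainConfig(epochs=2, batch_size=64), seed=1)
        assert history[1] < history[0]

    def test_same_seed_gives_identical_weights(self, corpus300, vocab300):
        cfg = tg.ModelConfig(vocab_size=len(vocab300), d_model=16, n_heads=2,
                             n_blocks=2, adapter_dim=4, max_len=48, dropout=0.1)
        sub = corpus300.records.head(100)

        def run():
            model = tg.ConditionalDecoder(cfg, seed=0)
            tg.pretrain(model, sub, vocab300,
                        PretrainConfig(epochs=2, batch_size=32), seed=9)
            return model.state_dict()
        a, b = run(), run()
        assert all(np.array_equal(a[k], b[k]) for k in a)

    def test_single_molecule_is_memorized(self, vocab300):
        cfg = tg.ModelConfig(vocab_size=len(vocab300), d_model=32, n_heads=2,
                             n_blocks=2, adapter_dim=8, max_len=48, dropout=0.0)
        model = tg.ConditionalDecoder(cfg, seed=0)
        one = tg.generate_corpus(n=1, seed=3).records
        history = tg.pretrain(
            model, one, vocab300,
            PretrainConfig(epochs=80, lr0=3e-3, decay_factor=0.99,
                           batch_size=1), seed=1)
        assert history[-1] < 0.2


class TestFinetuneLoop:
    def test_initial_validation_loss_equals_pretrained(
            self, pretrained_tiny, clone, target_sets, vocab300):
        """Zero-init adapters: fine-tuning starts from the pre-trained
        function, so the first validation pass must match exactly."""
        from targen.training import encode_dataset
        model = clone(pretrained_tiny)
        va = target_sets.records[target_sets.records["split"] == "valid"]
        tokens, targets, _ = encode_dataset(va, vocab300, model.config.max_len)
        before = evaluate_loss(model, tokens, np.zeros_like(targets))
        model.add_adapters((1, 2), seed=0)
        after = evaluate_loss(model, tokens, np.zeros_like(targets))
        assert after == pytest.approx(before, abs=1e-12)

    def test_early_stopping_fires_before_budget(
            self, pretrained_tiny, clone, target_sets, vocab300):
        model = clone(pretrained_tiny)
        tr = target_sets.records[target_sets.records["split"] == "train"].head(80)
        va = target_sets.records[target_sets.records["split"] == "valid"].head(30)
        cfg = FinetuneConfig(adapter_phase_len=15, main_phase_len=10,
                             max_epochs=60, cycle_len=60, n_cycles=1,
                             warmup_epochs=3, peak_lr=5e-3, batch_size=16,
                             patience=3)
        state = tg.finetune(model, tr, va, vocab300, cfg, seed=2)
        assert state.epoch < cfg.max_epochs - 1
        assert state.best_val == min(state.val_history)

    def test_missing_target_column_rejected(self, pretrained_tiny, clone,
                                            corpus300, vocab300):
        model = clone(pretrained_tiny)
        df = corpus300.records.drop(columns=["target"])
        with pytest.raises(ValueError, match="target"):
            tg.finetune(model, df, df, vocab300, FinetuneConfig(), seed=0)
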