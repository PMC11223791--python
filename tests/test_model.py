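import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ppiddg.model import (
    ConfigError,
    ModelConfig,
    SiameseNetwork,
    SpecError,
    TrainState,
    ablation_configs,
    alanine_scan,
    antisymmetric_loss,
    enumerate_multi,
    forward_pass,
    predict_multiple,
    predict_pair,
    predict_single,
    saturation_scan,
    train,
)
from ppiddg.pipeline import DirectionInputs, PairFeatures


class TestAntisymmetricLoss:
    @pytest.mark.parametrize("y", [-3.0, 0.0, 2.5])
    def test_zero_on_perfect_antisymmetric_prediction(self, y):
        assert antisymmetric_loss(f=y, r=-y, y=y) == 0.0

    def test_closed_form_example(self):
        # log cosh(0) + |2| = 2
        assert antisymmetric_loss(f=2.0, r=0.0, y=1.0) == pytest.approx(2.0)

    def test_against_numeric_log_cosh(self):
        expected = float(np.log(np.cosh(2.0)) + 2.0)
        assert antisymmetric_loss(f=3.0, r=-1.0, y=0.0) == pytest.approx(
            expected, abs=1e-12)

    def test_nonnegative_on_random_inputs(self, rng):
        for _ in range(200):
            f, r, y = rng.uniform(-30, 30, size=3)
            assert antisymmetric_loss(f, r, y) >= 0.0

    @given(
        f=st.floats(-1e3, 1e3),
        r=st.floats(-1e3, 1e3),
        y=st.floats(-1e3, 1e3),
    )
    @settings(deadline=None, derandomize=True, max_examples=300)
    def test_zero_only_on_antisymmetric_perfect_manifold(self, f, r, y):
        value = antisymmetric_loss(f, r, y)
        assert value >= 0.0
        if value == 0.0:
            assert (f - r) / 2.0 == pytest.approx(y, abs=1e-9)
            assert f + r == 0.0

    def test_stable_for_large_arguments(self):
        value = antisymmetric_loss(f=100.0, r=-100.0, y=-50.0)
        assert np.isfinite(value)
        assert value == pytest.approx(150.0 - np.log(2.0))

    def test_nonfinite_input_rejected(self):
        with pytest.raises(ValueError):
            antisymmetric_loss(np.inf, 0.0, 0.0)


def _random_pair(rng, embed_dim=6, n_cutoffs=3, tab_dim=5, n_nodes=4):
    def direction():
        a = np.zeros((n_nodes, n_nodes))
        for i in range(n_nodes - 1):
            a[i, i + 1] = a[i + 1, i] = 1.0
        return DirectionInputs(
            node_features=rng.standard_normal((n_nodes, embed_dim)),
            adjacency_norm=a / 2.0 + np.eye(n_nodes) * 0.5,
            signature=rng.integers(0, 20, size=n_cutoffs * 36).astype(float),
            tabular=rng.standard_normal(tab_dim),
        )
    return PairFeatures(forward=direction(), reverse=direction(), y=float(rng.normal()))


def _identity_normalizers(tab_dim, sig_dim):
    from ppiddg.features import Normalizer
    return (Normalizer(mean=np.zeros(tab_dim), scale=np.ones(tab_dim)),
            Normalizer(mean=np.zeros(sig_dim), scale=np.ones(sig_dim)))


class TestForwardPass:
    def test_direction_swap_negates_reported_exactly(self, rng):
        for trial in range(10):
            cfg = ModelConfig(seed=trial, gcn_hidden=(8,), gcn_out=4,
                              sig_channels=8, transformer_heads=2,
                              dense_hidden=(8,), dense_out=4, head_hidden=(8,))
            net = SiameseNetwork(cfg, embed_dim=6, n_cutoffs=3, tab_dim=5)
            normalizers = _identity_normalizers(5, 3 * 36)
            pair = _random_pair(rng)
            swapped = PairFeatures(forward=pair.reverse, reverse=pair.forward)
            p1 = forward_pass(net, normalizers, pair)
            p2 = forward_pass(net, normalizers, swapped)
            assert p1.reported + p2.reported == pytest.approx(0.0, abs=1e-5)
            assert p1.f == pytest.approx(p2.r) and p1.r == pytest.approx(p2.f)

    def test_zero_weights_give_bias_output(self, rng):
        cfg = ModelConfig(seed=0, gcn_hidden=(8,), gcn_out=4, sig_channels=8,
                          transformer_heads=2, dense_hidden=(8,), dense_out=4,
                          head_hidden=(8,))
        net = SiameseNetwork(cfg, embed_dim=6, n_cutoffs=3, tab_dim=5)
        for p in net.params.values():
            p.data[:] = 0.0
        pair = _random_pair(rng)
        pred = forward_pass(net, _identity_normalizers(5, 3 * 36), pair)
        assert pred.f == pred.r == 0.0
        assert pred.reported == 0.0

    def test_gcn_ablation_ignores_graph_perturbation(self, rng):
        cfg = ModelConfig(seed=0, use_gcn=False, sig_channels=8,
                          transformer_heads=2, dense_hidden=(8,), dense_out=4,
                          head_hidden=(8,))
        net = SiameseNetwork(cfg, embed_dim=6, n_cutoffs=3, tab_dim=5)
        normalizers = _identity_normalizers(5, 3 * 36)
        pair = _random_pair(rng)
        baseline = forward_pass(net, normalizers, pair)
        pair.forward.node_features = rng.standard_normal(pair.forward.node_features.shape)
        pair.forward.adjacency_norm = np.eye(pair.forward.adjacency_norm.shape[0])
        assert forward_pass(net, normalizers, pair).f == baseline.f

    def test_all_branches_disabled_is_config_error(self):
        with pytest.raises(ConfigError):
            ModelConfig(use_gcn=False, use_signature=False, use_dense=False)


class TestTraining:
    def test_deterministic_given_seed(self, small_data):
        _, _, _, dataset = small_data
        cfg = ModelConfig(seed=3, epochs=3)
        s1 = train(cfg, dataset)
        s2 = train(cfg, dataset)
        assert s1.train_history == s2.train_history
        p1 = predict_pair(s1, dataset.pairs[0])
        p2 = predict_pair(s2, dataset.pairs[0])
        assert p1.f == p2.f and p1.r == p2.r

    def test_loss_decreases_on_synthetic_data(self, quick_state):
        assert quick_state.train_history[-1] < quick_state.train_history[0]

    def test_empty_training_fold_rejected(self, small_data):
        _, _, _, dataset = small_data
        with pytest.raises(Exception, match="empty training fold"):
            train(ModelConfig(epochs=1), dataset, train_ids=set())

    def test_every_single_branch_ablation_trains_to_finite_loss(self, small_data):
        _, _, _, dataset = small_data
        for name, cfg in ablation_configs(ModelConfig(seed=0, epochs=2)).items():
            state = train(cfg, dataset)
            assert np.isfinite(state.train_history[-1]), name

    def test_antisymmetry_penalty_shrinks_bias(self, small_data):
        # compared against an ablated loss without the |f + r| term, the
        # trained model's mean(f + r) must be closer to zero
        import ppiddg.model as model_mod
        from ppiddg.autodiff import concat

        _, _, _, dataset = small_data
        cfg = ModelConfig(seed=0, epochs=8)
        full = train(cfg, dataset)

        # ablation: retrain with the anti-symmetry term removed
        original = model_mod.train

        def patched_losses(net, normalized, labels, batch):
            losses = []
            for idx in batch:
                fwd, rev = normalized[idx]
                f = net.subnetwork(fwd)
                r = net.subnetwork(rev)
                losses.append(((f - r) / 2.0 - labels[idx]).logcosh())
            return losses
        # train a sibling model with the plain regression loss
        from ppiddg.autodiff import Adam
        from ppiddg.features import Normalizer
        from ppiddg.model import SiameseNetwork, _normalize_inputs

        tab_rows = np.array([d.tabular for p in dataset.pairs
                             for d in (p.forward, p.reverse)])
        sig_rows = np.array([d.signature for p in dataset.pairs
                             for d in (p.forward, p.reverse)])
        tabn, sign = Normalizer.fit(tab_rows), Normalizer.fit(sig_rows)
        net = SiameseNetwork(cfg, dataset.embed_dim, dataset.n_cutoffs,
                             len(dataset.tabular_columns))
        opt = Adam(net.parameters(), lr=cfg.learning_rate)
        rng_local = np.random.default_rng(cfg.seed)
        normalized = [_normalize_inputs((tabn, sign), p) for p in dataset.pairs]
        labels = [p.y for p in dataset.pairs]
        for _ in range(cfg.epochs):
            order = rng_local.permutation(len(dataset.pairs))
            for start in range(0, len(order), cfg.batch_size):
                batch = order[start:start + cfg.batch_size]
                losses = patched_losses(net, normalized, labels, batch)
                total = concat([ls.reshape(1) for ls in losses]).mean()
                opt.zero_grad()
                total.backward()
                opt.step()

        full_net = full.network()
        bias_full = np.mean([
            (lambda p: p.f + p.r)(predict_pair(full, pair, net=full_net))
            for pair in dataset.pairs
        ])
        bias_plain = np.mean([
            (lambda p: p.f + p.r)(forward_pass(net, (full.tab_normalizer,
                                                     full.sig_normalizer), pair))
            for pair in dataset.pairs
        ])
        assert abs(bias_full) < abs(bias_plain)
        assert original is model_mod.train  # nothing was monkeypatched


class TestDrivers:
    def test_predict_multiple_is_exact_sum_of_singles(self, small_data, quick_state):
        records, structures, pipeline, _ = small_data
        structure = structures[records[0].complex_id]
        from ppiddg.structures import THREE_TO_ONE, MutationSpec
        keys = sorted(pg_interface(structure))[:2]
        specs = [
            MutationSpec(chain_id=k.chain_id,
                         wt_aa=THREE_TO_ONE[structure.residue_name(k)],
                         position=k.residue_seq,
                         mut_aa="W" if THREE_TO_ONE[structure.residue_name(k)] != "W" else "F")
            for k in keys
        ]
        ordered = sorted(specs, key=lambda s: (s.residue_key, s.mut_aa))
        singles = [predict_single(quick_state, structure, s, pipeline).reported
                   for s in ordered]
        combined = predict_multiple(quick_state, structure, specs, pipeline)
        assert combined == sum(singles)  # bitwise
        permuted = predict_multiple(quick_state, structure,
                                    list(reversed(specs)), pipeline)
        assert permuted == combined
        assert predict_multiple(quick_state, structure, ordered[:1], pipeline) \
            == singles[0]

    def test_predict_multiple_input_validation(self, small_data, quick_state):
        records, structures, pipeline, _ = small_data
        structure = structures[records[0].complex_id]
        with pytest.raises(SpecError):
            predict_multiple(quick_state, structure, [], pipeline)
        spec = records[0].specs[0]
        from dataclasses import replace
        other = replace(spec, mut_aa="W" if spec.mut_aa != "W" else "F")
        with pytest.raises(SpecError):
            predict_multiple(quick_state, structure, [spec, other], pipeline)

    def test_alanine_scan_skips_alanine_and_keeps_glycine(self, small_data, quick_state):
        records, structures, pipeline, _ = small_data
        structure = structures[records[0].complex_id]
        iface = pg_interface(structure)
        from ppiddg.structures import THREE_TO_ONE
        wt_letters = [THREE_TO_ONE[structure.residue_name(k)] for k in sorted(iface)]
        table = alanine_scan(quick_state, structure, pipeline)
        assert len(table) == sum(1 for w in wt_letters if w != "A")
        assert (table["mut"] == "A").all()

    def test_saturation_scan_has_nineteen_rows_per_residue(self, small_data, quick_state):
        records, structures, pipeline, _ = small_data
        structure = structures[records[0].complex_id]
        table = saturation_scan(quick_state, structure, pipeline)
        assert len(table) == 19 * len(pg_interface(structure))
        per_residue = table.groupby(["chain", "position"]).size()
        assert (per_residue == 19).all()

    def test_enumeration_cap_and_determinism(self, small_data, quick_state):
        records, structures, pipeline, _ = small_data
        structure = structures[records[0].complex_id]
        inc, dec = enumerate_multi(quick_state, structure, pipeline,
                                   side={"A"}, order=2, top_k=10)
        inc2, _ = enumerate_multi(quick_state, structure, pipeline,
                                  side={"A"}, order=2, top_k=10)
        assert len(inc) == 10 and len(dec) == 10
        assert inc["predicted_ddg"].is_monotonic_decreasing
        assert dec["predicted_ddg"].is_monotonic_increasing
        assert inc.equals(inc2)

    def test_enumeration_requires_enough_positions(self, small_data, quick_state):
        records, structures, pipeline, _ = small_data
        structure = structures[records[0].complex_id]
        with pytest.raises(SpecError):
            enumerate_multi(quick_state, structure, pipeline, side={"Z"}, order=2)


class TestCheckpoint:
    def test_save_load_round_trip_is_bit_identical(self, small_data, quick_state,
                                                   tmp_path):
        _, _, _, dataset = small_data
        path = tmp_path / "model.npz"
        quick_state.save(str(path))
        loaded = TrainState.load(str(path))
        for pair in dataset.pairs[:5]:
            a = predict_pair(quick_state, pair)
            b = predict_pair(loaded, pair)
            assert a.f == b.f and a.r == b.r


def pg_interface(structure):
    from ppiddg.interface import interface_residues
    return interface_residues(structure)
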