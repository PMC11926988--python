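"""Full-network contracts: wiring, survival head, ablations, checkpoints."""

import numpy as np
import pytest

from dualsurv import (PatientRecord, RunConfig, build_model, risk_score,
                      survival_function)
from dualsurv.model import SurvivalFusionNet
from dualsurv.train import ABLATION_TOGGLES


def toy_bags(rng, n=3, k=2):
    return rng.normal(size=(n, 768)), rng.normal(size=(k, 256))


class TestSurvivalFunction:
    def test_hand_product(self):
        assert np.allclose(survival_function([0.5, 0.5]), [0.5, 0.25])

    def test_zero_hazards_give_unit_survival(self):
        assert np.allclose(survival_function(np.zeros(4)), 1.0)

    def test_four_interval_hand_case(self):
        S = survival_function([0.1, 0.2, 0.3, 0.4])
        assert np.allclose(S, [0.9, 0.72, 0.504, 0.3024], atol=1e-12)

    def test_out_of_range_hazard_rejected(self):
        with pytest.raises(ValueError):
            survival_function([0.5, 1.2])


class TestRiskScore:
    def test_hand_case(self):
        assert risk_score([0.5, 0.25]) == -0.75

    def test_bounds(self):
        t = 4
        assert risk_score(np.zeros(t)) == 0.0          # hazards -> 1
        assert risk_score(np.ones(t)) == -t            # hazards -> 0

    def test_strictly_increasing_in_every_hazard(self, rng):
        h = rng.uniform(0.05, 0.95, size=4)
        base = risk_score(survival_function(h))
        for j in range(4):
            bumped = h.copy()
            bumped[j] += 0.01
            assert risk_score(survival_function(bumped)) > base


class TestBuildModel:
    def test_default_head_has_four_intervals(self):
        model = build_model(RunConfig(d_model=16, d_state=4))
        assert model._params["head_out.w"].shape == (16, 4)

    def test_toy_model_runs_forward(self, toy_config, rng):
        model = build_model(toy_config)
        pred = model.predict(toy_bags(rng))
        assert pred.hazards.shape == (4,)

    def test_same_seed_gives_identical_parameters(self, toy_config):
        a = build_model(toy_config)
        b = build_model(toy_config)
        for k in a.parameters():
            assert np.array_equal(a.parameters()[k].data,
                                  b.parameters()[k].data), k


class TestForward:
    def test_hazards_bounded_and_survival_monotone(self, toy_config, rng):
        model = build_model(toy_config)
        for _ in range(100):
            n, k = rng.integers(1, 6, size=2)
            pred = model.predict((rng.normal(size=(n, 768)),
                                  rng.normal(size=(k, 256))))
            assert np.all((pred.hazards > 0) & (pred.hazards < 1))
            assert np.all(np.diff(pred.survival) <= 0)
            assert np.all((pred.survival > 0) & (pred.survival <= 1))

    def test_permutation_invariant_without_token_order_sensitivity(self, rng):
        """With the order-sensitive stages off, patch order cannot matter.

        Attention, pooling and pointwise maps commute with a shared row
        permutation; the scan does not — so disable it (and the depthwise
        token convs via the mixers) and check exact invariance.
        """
        cfg = RunConfig(d_model=16, d_state=4, seed=1, use_bimamba=False,
                        use_idconv=False, use_ste=False)
        model = build_model(cfg)
        P, G = toy_bags(rng, n=6, k=3)
        base = model.predict((P, G))
        perm = model.predict((P[rng.permutation(6)], G))
        assert np.allclose(base.hazards, perm.hazards, atol=1e-6)

    def test_order_matters_when_scan_enabled(self, rng):
        cfg = RunConfig(d_model=16, d_state=4, seed=1)
        model = build_model(cfg)
        P, G = toy_bags(rng, n=6, k=3)
        base = model.predict((P, G))
        perm = model.predict((P[::-1].copy(), G))
        assert not np.allclose(base.reps.h, perm.reps.h, atol=1e-10)

    def test_no_cross_zeroes_cross_representations(self, toy_config, rng):
        model = build_model(toy_config.replace(use_cross=False))
        pred = model.predict(toy_bags(rng))
        assert np.allclose(pred.reps.h_hat, 0.0)
        assert np.allclose(pred.reps.g_hat, 0.0)

    @pytest.mark.parametrize("n,k", [(1, 1), (5, 50), (4096, 4)])
    def test_bag_size_robustness(self, rng, n, k):
        cfg = RunConfig(d_model=8, d_state=2, reduction=2, seed=0)
        model = build_model(cfg)
        pred = model.predict((rng.normal(size=(n, 768)),
                              rng.normal(size=(k, 256))))
        assert np.all(np.isfinite(pred.hazards))

    def test_non_finite_input_raises_with_stage_name(self, toy_config, rng):
        model = build_model(toy_config)
        P, G = toy_bags(rng)
        P[0, 0] = np.nan
        with pytest.raises((ValueError, FloatingPointError)):
            model.predict((P, G))


class TestAblationWirings:
    def test_each_toggle_changes_the_computation(self, rng):
        cfg = RunConfig(d_model=16, d_state=4, seed=2)
        P, G = toy_bags(rng, n=4, k=3)

        def reps_of(config):
            r = build_model(config).predict((P, G)).reps
            return np.concatenate([r.h, r.h_hat, r.g, r.g_hat])

        base = reps_of(cfg)
        for name, override in ABLATION_TOGGLES.items():
            if name == "no_alignment":
                continue  # loss-side toggle; same forward graph
            assert not np.allclose(reps_of(cfg.replace(**override)), base,
                                   atol=1e-10), name

    def test_toggle_list_covers_nine_wirings(self):
        assert len(ABLATION_TOGGLES) == 9


class TestGradients:
    def test_end_to_end_gradients_finite(self, rng):
        from dualsurv.losses import alignment_loss, nll_survival_loss
        cfg = RunConfig(d_model=8, d_state=2, reduction=2, seed=3)
        model = build_model(cfg)
        out = model.forward_tensors(*toy_bags(rng, n=4, k=3))
        loss = nll_survival_loss(out["hazards"].reshape(1, -1), [2], [0]) \
            + 0.03 * alignment_loss(out["h"], out["h_hat"], out["g"],
                                    out["g_hat"])
        loss.backward()
        for name, p in model.parameters().items():
            assert p.grad is None or np.all(np.isfinite(p.grad)), name


class TestCheckpoint:
    def test_round_trip_preserves_predictions(self, toy_config, rng,
                                              tmp_path):
        model = build_model(toy_config)
        bags = toy_bags(rng)
        before = model.predict(bags).hazards
        path = tmp_path / "model.npz"
        model.save(path)
        restored = SurvivalFusionNet.load(path)
        assert np.allclose(restored.predict(bags).hazards, before, atol=0)
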