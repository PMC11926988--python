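"""State-space primitives: discretization, scan/convolution duality, Bi-Mamba."""

import numpy as np
import pytest

from dualsurv.autodiff import Tensor
from dualsurv.ssm import (BiMamba, DiscreteSSM, SSMParams, bimamba_reference,
                          ssm_conv_apply, ssm_conv_kernel, ssm_scan,
                          zoh_discretize)


class TestZOHDiscretize:
    @pytest.mark.parametrize("D,delta,E,dbar,ebar", [
        (1.0, np.log(2.0), 1.0, 2.0, 1.0),           # (1/ln2)(2-1)·ln2·1
        (-1.0, 1.0, 1.0, np.exp(-1), 1 - np.exp(-1)),
        (0.0, 0.3, 2.0, 1.0, 0.6),                   # removable singularity
    ])
    def test_scalar_analytic_cases(self, D, delta, E, dbar, ebar):
        disc = zoh_discretize(SSMParams(D=D, E=E, F=1.0, delta=delta))
        assert np.allclose(disc.Dbar, dbar, atol=1e-12)
        assert np.allclose(disc.Ebar, ebar, atol=1e-12)

    def test_dbar_is_elementwise_exponential(self, rng):
        D = -np.abs(rng.normal(size=8)) - 0.01
        delta = 0.37
        disc = zoh_discretize(SSMParams(D=D, E=np.ones(8), F=np.ones(8),
                                        delta=delta))
        assert np.allclose(disc.Dbar, np.exp(delta * D), atol=1e-12)

    def test_ebar_continuous_across_small_argument_branch(self):
        # |delta*D| = 1e-8 vs the limit formula delta*E
        disc = zoh_discretize(SSMParams(D=1e-4, E=3.0, F=1.0, delta=1e-4))
        assert abs(disc.Ebar[0] - 1e-4 * 3.0) <= 1e-9

    def test_negative_diagonal_is_stable(self, rng):
        D = -np.abs(rng.normal(size=16)) - 1e-6
        disc = zoh_discretize(SSMParams(D=D, E=np.ones(16), F=np.ones(16),
                                        delta=0.9))
        assert np.all(np.abs(disc.Dbar) < 1.0)

    def test_nonpositive_delta_rejected(self):
        with pytest.raises(ValueError):
            SSMParams(D=1.0, E=1.0, F=1.0, delta=0.0)


class TestScanAndConvolution:
    def test_hand_recurrence(self):
        disc = DiscreteSSM(Dbar=np.array([0.5]), Ebar=np.array([1.0]))
        y = ssm_scan(disc, np.array([1.0]), np.array([1.0, 0.0, 0.0]))
        assert np.allclose(y, [1.0, 0.5, 0.25])

    def test_zero_input_gives_zero_output(self):
        disc = DiscreteSSM(Dbar=np.array([0.9, 0.5]), Ebar=np.array([1.0, 2.0]))
        assert np.allclose(ssm_scan(disc, np.ones(2), np.zeros(7)), 0.0)

    def test_kernel_analytic_powers(self):
        disc = DiscreteSSM(Dbar=np.array([0.5]), Ebar=np.array([1.0]))
        assert np.allclose(ssm_conv_kernel(disc, np.array([1.0]), 3),
                           [1.0, 0.5, 0.25])

    def test_zero_output_map_gives_zero_kernel(self):
        disc = DiscreteSSM(Dbar=np.array([0.5, 0.2]), Ebar=np.array([1.0, 1.0]))
        assert np.allclose(ssm_conv_kernel(disc, np.zeros(2), 5), 0.0)

    def test_kernel_matches_matrix_power_oracle(self, rng):
        ns, M = 4, 6
        Dbar = rng.uniform(-0.9, 0.9, size=ns)
        Ebar = rng.normal(size=ns)
        F = rng.normal(size=ns)
        kernel = ssm_conv_kernel(DiscreteSSM(Dbar=Dbar, Ebar=Ebar), F, M)
        oracle = [F @ (np.diag(Dbar ** m) @ Ebar) for m in range(M)]
        assert np.allclose(kernel, oracle, atol=1e-10)

    def test_invalid_kernel_length(self):
        with pytest.raises(ValueError):
            ssm_conv_kernel(DiscreteSSM(Dbar=np.ones(1), Ebar=np.ones(1)),
                            np.ones(1), 0)

    def test_conv_apply_hand_case_and_identity(self):
        y = ssm_conv_apply([1.0, 0.0, 0.0, 0.0], [1.0, 0.5, 0.25])
        assert np.allclose(y, [1.0, 0.5, 0.25, 0.0])
        x = np.arange(5.0)
        assert np.allclose(ssm_conv_apply(x, [1.0]), x)

    @pytest.mark.parametrize("seed", range(10))
    def test_scan_convolution_duality(self, seed):
        """A time-invariant scan equals causal convolution with the M=L kernel."""
        rng = np.random.default_rng(seed)
        ns = rng.integers(1, 9)
        L = rng.integers(1, 33)
        params = SSMParams(D=-np.abs(rng.normal(size=ns)) - 0.05,
                           E=rng.normal(size=ns), F=rng.normal(size=ns),
                           delta=rng.uniform(0.05, 1.0))
        disc = zoh_discretize(params)
        x = rng.normal(size=L)
        y_scan = ssm_scan(disc, params.F, x)
        y_conv = ssm_conv_apply(x, ssm_conv_kernel(disc, params.F, L))
        assert np.max(np.abs(y_scan - y_conv)) <= 1e-5


class TestBiMamba:
    def test_single_token_directions_agree_when_tied(self, rng):
        block = BiMamba(dim=6, d_state=4, rng=rng, tie_directions=True)
        x = Tensor(rng.normal(size=(1, 6)))
        _, (y_f, y_b) = block.forward(x, return_directions=True)
        assert np.allclose(y_f.data, y_b.data, atol=1e-12)

    def test_zero_input_zero_biases_gives_zero_output(self, rng):
        block = BiMamba(dim=4, d_state=2, rng=rng)
        for name, p in block.params.items():
            if name.endswith("_b") or name.endswith("proj_b"):
                p.data[:] = 0.0
        out = block(Tensor(np.zeros((5, 4))))
        assert np.allclose(out.data, 0.0, atol=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_per_timestep_recurrence_oracle(self, seed):
        rng = np.random.default_rng(seed)
        L = int(rng.integers(1, 17))
        C = int(rng.integers(2, 17))
        block = BiMamba(dim=C, d_state=int(rng.integers(1, 9)),
                        conv_width=int(rng.integers(1, 5)), rng=rng)
        x = rng.normal(size=(L, C))
        fast = block(Tensor(x)).data
        slow = bimamba_reference(block, x)
        assert np.max(np.abs(fast - slow)) <= 1e-5

    def test_reversal_equivariance_with_tied_directions(self, rng):
        block = BiMamba(dim=6, d_state=4, rng=rng, tie_directions=True)
        x = rng.normal(size=(7, 6))
        # forward branch on reversed input == reversed backward branch
        _, (y_f_rev, _) = block.forward(Tensor(x[::-1].copy()),
                                        return_directions=True)
        _, (_, y_b) = block.forward(Tensor(x), return_directions=True)
        assert np.allclose(y_f_rev.data, y_b.data[::-1], atol=1e-10)

    def test_non_finite_input_rejected(self, rng):
        block = BiMamba(dim=4, d_state=2, rng=rng)
        bad = np.zeros((3, 4))
        bad[1, 1] = np.nan
        with pytest.raises(ValueError):
            block(Tensor(bad))
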