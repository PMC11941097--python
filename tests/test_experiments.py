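"""Sweep drivers, grid searches, and protocol-level properties (scaled down)."""

import warnings

import numpy as np
import pytest
from scipy.stats import spearmanr

from snnxor import (
    NoiseSpec,
    SweepConfig,
    TaskBoundary,
    build_ann_xor,
    build_nonleaky_snn_xor,
    build_snn_xor,
    compare_modes,
    firing_rate_map,
    grid_search_boundary,
    grid_search_gains,
    output_surface,
    sweep_noise,
)
from snnxor.experiments import boundary_grid, input_grid, run_metadata
from snnxor.task import AccuracySurface

warnings.filterwarnings("ignore", message="all-zero output surface")


def idealized_ann_surface(n=501):
    x = np.linspace(0, 1, n)
    X0, X1 = np.meshgrid(x, x, indexing="ij")
    return AccuracySurface(x, x, np.abs(X0 - X1))


class TestGainSearch:
    def test_single_candidate_grid_returns_it(self):
        res = grid_search_gains(kind="ann", input_gains=[4], weight_gains=[40])
        assert (res.best_input_gain, res.best_weight_gain) == (4, 40)

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            grid_search_gains(input_gains=[], weight_gains=[])

    def test_ann_accuracy_is_gain_invariant_and_ties_break_low(self):
        # the normalized ReLU surface does not depend on positive gains, so
        # every candidate ties and the smallest pair is returned; h = 0.33
        # avoids exact ties with the 0.05-step grid differences, where gain
        # rounding could otherwise flip the >= comparison
        res = grid_search_gains(kind="ann", boundary=TaskBoundary(0.46, 0.33),
                                input_gains=[2, 5], weight_gains=[10, 50])
        assert (res.best_input_gain, res.best_weight_gain) == (2, 10)
        assert res.table.accuracy.nunique() == 1

    def test_snn_search_is_exhaustive_argmax(self):
        res = grid_search_gains(kind="snn", input_gains=[3, 5], weight_gains=[50, 110],
                                T=1.0)
        assert len(res.table) == 4
        assert res.best_accuracy == res.table.accuracy.max()
        row = res.table.loc[res.table.accuracy.idxmax()]
        assert res.best_accuracy == pytest.approx(row.accuracy)


class TestBoundarySearch:
    def test_perfect_indicator_surface_ties_break_to_smallest(self):
        x = np.linspace(0, 1, 21)
        raw = np.logical_xor(x[:, None] >= 0.5, x[None, :] >= 0.5).astype(float)
        surf = AccuracySurface(x, x, raw)
        best, acc = grid_search_boundary(surf, np.array([0.48, 0.5]), np.array([0.5, 0.9]))
        assert acc == 1.0
        assert (best.b, best.h) == (0.48, 0.5)  # 0.48 also consistent on this grid

    def test_idealized_ann_peak_in_nondegenerate_band(self):
        # restricted to b in [0.1, 0.9], the |x0 - x1| surface peaks near 0.84
        surf = idealized_ann_surface()
        bs = boundary_grid()
        bs = bs[(bs >= 0.1) & (bs <= 0.9)]
        _, acc = grid_search_boundary(surf, bs, boundary_grid())
        assert acc == pytest.approx(0.84, abs=0.01)

    def test_many_ann_boundaries_near_the_peak(self):
        surf = idealized_ann_surface()
        bs = boundary_grid()
        bs = bs[(bs >= 0.1) & (bs <= 0.9)]
        grid = surf.accuracy_grid(bs, boundary_grid())
        assert np.sum(grid >= grid.max() - 0.01) > 10


class TestSweep:
    CFG = dict(input_gain=5, weight_gain=110, tau_syn=1.0,
               noise_family="multiplicative_white", mode="common",
               boundaries=((0.36, 0.4), (0.46, 0.3)), T=1.0, grid_n=11)

    def test_zero_noise_repeats_are_identical(self):
        cfg = SweepConfig(D_values=(0.0,), repeats=3, **self.CFG)
        res = sweep_noise(cfg)
        assert np.all(res.sd == 0.0)
        assert np.all(res.accuracy[:, :, 0:1] == res.accuracy)

    def test_low_spread_across_repeats_at_moderate_noise(self):
        # normalized per run, accuracy varies little between seeds
        cfg = SweepConfig(D_values=(2.0,), repeats=6, T=2.0, base_seed=3,
                          **{k: v for k, v in self.CFG.items() if k != "T"})
        res = sweep_noise(cfg)
        assert np.all(res.sd < 0.03)

    def test_rerun_is_bit_identical(self):
        cfg = SweepConfig(D_values=(0.0, 1.0), repeats=2, base_seed=9, **self.CFG)
        a = sweep_noise(cfg).to_frame().to_csv(index=False)
        b = sweep_noise(cfg).to_frame().to_csv(index=False)
        assert a == b

    def test_frame_layout(self):
        cfg = SweepConfig(D_values=(0.0,), repeats=2, **self.CFG)
        frame = sweep_noise(cfg).to_frame()
        assert list(frame.columns) == ["b", "h", "D", "noise_family", "mode",
                                       "tau_syn", "repeat", "accuracy"]
        assert len(frame) == 2 * 1 * 2
        assert frame.accuracy.between(0, 1).all()

    def test_config_roundtrip(self):
        cfg = SweepConfig(D_values=(0.0, 2.5), repeats=2, **self.CFG)
        assert SweepConfig.from_dict(cfg.to_dict()) == cfg


class TestStochasticResonance:
    def test_noise_rescues_misset_boundary(self):
        """Common multiplicative noise lifts accuracy at a deliberately poor
        boundary above its noiseless value (dynamical synapse, tau_syn = 20 ms)."""
        cfg = SweepConfig(input_gain=5, weight_gain=25, synapse="dynamical",
                          tau_syn=20.0, noise_family="multiplicative_white",
                          mode="common", D_values=(0.0, 2.0, 5.0),
                          boundaries=((0.3, 0.5),), repeats=3, T=2.0, base_seed=7)
        res = sweep_noise(cfg)
        mean = res.mean[0]
        assert mean[1:].max() > mean[0] + 0.02

    def test_best_boundary_tracking_per_noise_level(self):
        cfg = SweepConfig(input_gain=5, weight_gain=25, tau_syn=20.0,
                          noise_family="multiplicative_white", mode="common",
                          D_values=(0.0, 5.0), boundaries=((0.46, 0.9), (0.3, 0.5)),
                          repeats=2, T=1.0, base_seed=1, grid_n=11)
        best = sweep_noise(cfg).best_boundary_per_D()
        assert len(best) == 2
        assert all(isinstance(b, TaskBoundary) for b in best)


class TestCompareModes:
    def test_zero_noise_modes_coincide(self):
        cfg = SweepConfig(input_gain=5, weight_gain=110, tau_syn=1.0,
                          noise_family="multiplicative_white",
                          D_values=(0.0,), boundaries=((0.36, 0.4),),
                          repeats=2, T=1.0, grid_n=11)
        res = compare_modes(cfg)
        assert np.array_equal(res["common"].accuracy, res["independent"].accuracy)

    def test_gap_small_at_high_tau_syn_moderate_noise(self):
        # long PSC integration washes out per-draw differences between modes
        cfg = SweepConfig(input_gain=5, weight_gain=25, tau_syn=20.0,
                          noise_family="multiplicative_white",
                          D_values=(1.0,), boundaries=((0.36, 0.4), (0.46, 0.3)),
                          repeats=3, T=2.0, base_seed=7)
        res = compare_modes(cfg)
        gap = np.abs(res["common"].mean - res["independent"].mean)
        assert np.all(gap < 0.05)

    def test_gap_grows_with_noise_at_short_tau_syn(self):
        cfg = SweepConfig(input_gain=5, weight_gain=110, tau_syn=1.0,
                          noise_family="multiplicative_white",
                          D_values=(1.0, 2.0, 5.0), boundaries=((0.3, 0.5),),
                          repeats=3, T=2.0, base_seed=7)
        res = compare_modes(cfg)
        gap = np.abs(res["common"].mean - res["independent"].mean)[0]
        assert gap[0] < gap[1] < gap[2]


class TestFiringRateMap:
    def test_zero_surface_without_drive(self):
        spec = build_snn_xor(5, 110)
        frame = firing_rate_map(spec, None, T=0.5, grid_n=5)
        assert frame.values[0, 0] == 0.0  # origin: 18 pA base only

    def test_multiplicative_noise_shifts_sensitivity_to_weaker_inputs(self):
        # minimal input magnitude eliciting > 1 Hz output drops at D = 5
        spec = build_snn_xor(5, 25, tau_syn=20.0)
        quiet = firing_rate_map(spec, None, T=2.0, grid_n=21)
        noisy = firing_rate_map(
            spec, NoiseSpec(family="multiplicative_white", D=5.0, mode="common"),
            T=2.0, seed=4, grid_n=21)

        def min_active_input(frame):
            x = frame.index.values
            col = frame.values[:, 0]  # slice x1 = 0
            active = np.nonzero(col > 1.0)[0]
            return x[active[0]] if active.size else np.inf

        assert min_active_input(noisy) < min_active_input(quiet)

    def test_dynamical_high_tau_keeps_sharper_contrast_than_static(self):
        # surface variance as the contrast measure, at high common noise
        ns = NoiseSpec(family="multiplicative_white", D=5.0, mode="common")
        dyn = output_surface(build_snn_xor(5, 25, tau_syn=20.0), ns, T=2.0, seed=9)
        stat = output_surface(build_snn_xor(5, 25, synapse="static"), ns, T=2.0, seed=9)
        assert dyn.normalized.var() > stat.normalized.var()

    def test_higher_tau_syn_raises_noiseless_contrast(self):
        s5 = output_surface(build_snn_xor(5, 25, tau_syn=5.0), T=2.0)
        s20 = output_surface(build_snn_xor(5, 25, tau_syn=20.0), T=2.0)
        assert s20.normalized.var() > s5.normalized.var()


class TestNonLeakyComparison:
    def test_noisy_nonleaky_static_surface_is_ann_like(self):
        """Pure integrators with one-sided clamping approximate the ReLU
        separation, the more closely the stronger the noise."""
        ann = output_surface(build_ann_xor(6, 111))
        nl = build_nonleaky_snn_xor(6, 111)
        ns = NoiseSpec(family="additive_white", D=5.0, mode="independent")
        noisy = output_surface(nl, ns, T=2.0, seed=2)
        rho = spearmanr(noisy.normalized.ravel(), ann.normalized.ravel()).statistic
        assert rho > 0.9


class TestUtilities:
    def test_input_grid_default_step(self):
        g = input_grid()
        assert g.size == 21
        assert g[1] - g[0] == pytest.approx(0.05)

    def test_boundary_grid_excludes_endpoints(self):
        g = boundary_grid()
        assert g.min() == pytest.approx(0.02)
        assert g.max() <= 0.98 + 1e-12
        assert 0.0 not in g and 1.0 not in g

    def test_run_metadata_hash_is_stable(self):
        cfg = SweepConfig(D_values=(0.0,), repeats=1, boundaries=((0.5, 0.5),))
        a = run_metadata(cfg, seed=1)
        b = run_metadata(cfg, seed=2)
        assert a["config_sha256"] == b["config_sha256"]
        assert a["seed"] != b["seed"]
        assert "snnxor_version" in a
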