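"""Multiplex plans and the weighted global Gerchberg–Saxton designer."""

import numpy as np
import pytest

import hilomfm as hm
from hilomfm.phase_design import PlanError, _plane_phase


@pytest.fixture(scope="module")
def converged_pair(nine_plan):
    """(phi0, converged mask) for the nine-plane plan, 10 GS iterations."""
    cfg = hm.default_gs_config(max_iter=11)
    phi0 = hm.init_superposition(nine_plan, cfg)
    mask = hm.wggs_optimize(nine_plan, cfg, phi0)
    return phi0, mask


class TestPlanFromSpacings:
    def test_nine_plane_symmetric_layout(self, train256):
        """Equal 0.4 um spacings, centred: dl = -1.6 .. +1.6 um in 0.4 steps."""
        plan = hm.plan_from_spacings([0.4] * 8, train256, anchor="center")
        dls = [p.delta_l for p in plan.planes]
        assert np.allclose(dls, np.arange(-4, 5) * 0.4)
        assert np.allclose(
            [p.delta_L for p in plan.planes], np.arange(-4, 5) * 0.4 * 60.0**2
        )

    def test_single_plane_degenerate(self, train256):
        plan = hm.plan_from_spacings([], train256, anchor=0, tile_order=[(1, 1)])
        assert [p.delta_l for p in plan.planes] == [0.0]
        assert [p.delta_L for p in plan.planes] == [0.0]

    def test_first_plane_anchor_cumulative(self, train256):
        plan = hm.plan_from_spacings([0.5, 1.0], train256, anchor=0)
        assert [p.delta_l for p in plan.planes] == [0.0, 0.5, 1.5]

    def test_rejects_bad_inputs(self, train256):
        with pytest.raises(PlanError):
            hm.plan_from_spacings([0.4, -0.1], train256)
        with pytest.raises(PlanError):
            hm.plan_from_spacings([0.4], train256, tile_order=[(0, 0), (0, 0)])
        with pytest.raises(PlanError):  # zero-weight plane away from dL = 0
            hm.plan_from_spacings([0.4], train256, anchor=0, weights=[1.0, 0.0])

    def test_zero_order_plane_identified(self, nine_plan):
        zp = nine_plan.zero_order_plane()
        assert zp is not None and zp.delta_l == 0.0 and zp.tile_rc == (1, 1)


class TestInitSuperposition:
    def test_single_plane_equals_its_phase_term(self, train256):
        plan = hm.plan_from_spacings(
            [], train256, anchor=0, tile_order=[(0, 2)], weights=[1.0]
        )
        cfg = hm.default_gs_config()
        mask = hm.init_superposition(plan, cfg)
        expected = np.mod(_plane_phase(plan, plan.planes[0], cfg.wavelength), 2 * np.pi)
        ap = train256.aperture_mask()
        delta = np.angle(np.exp(1j * (mask.phase[ap] - expected[ap])))
        assert np.max(np.abs(delta)) < 1e-9

    def test_two_opposite_tilts_give_two_spots(self, train256):
        plan = hm.plan_from_spacings(
            [0.4], train256, anchor=0, tile_order=[(1, 0), (1, 2)], weights=[1.0, 1.0]
        )
        cfg = hm.default_gs_config()
        mask = hm.init_superposition(plan, cfg)
        resp = hm.simulate_mask_response(mask, plan)
        table = resp["energy_table"]
        # each plane's own tile receives a dominant share of its energy
        assert table[0, 0] > 0.2 and table[1, 1] > 0.2

    def test_distinct_depths_resolved_at_own_plane(self, train256):
        """Two planes far apart axially: the (plane, tile) energy argmax is
        the matching pair for both."""
        plan = hm.plan_from_spacings(
            [18.0], train256, anchor="center", tile_order=[(1, 0), (1, 2)],
            weights=[1.0, 1.0],
        )
        cfg = hm.default_gs_config()
        mask = hm.init_superposition(plan, cfg)
        table = hm.simulate_mask_response(mask, plan)["energy_table"]
        assert np.argmax(table[0]) == 0 and np.argmax(table[1]) == 1

    def test_nyquist_violation_names_tile(self, train256):
        plan = hm.plan_from_spacings(
            [0.4] * 8, train256, tile_shape=(9, 9),
            tile_order=[(r, 8) for r in range(9)],
        )
        with pytest.raises(PlanError, match="Nyquist"):
            hm.init_superposition(plan, hm.default_gs_config())


class TestWggsOptimize:
    def test_identity_target_keeps_flat_mask(self, train256):
        """A single on-axis plane needs no modulation: the mask stays flat."""
        plan = hm.plan_from_spacings([], train256, anchor=0, tile_order=[(1, 1)])
        cfg = hm.default_gs_config(max_iter=6)
        flat = hm.PhaseMask(np.zeros(train256.slm_shape), train256, cfg.wavelength)
        mask = hm.wggs_optimize(plan, cfg, flat)
        ap = train256.aperture_mask()
        mean_dir = np.angle(np.mean(np.exp(1j * mask.phase[ap])))
        spread = np.angle(np.exp(1j * (mask.phase[ap] - mean_dir)))
        assert np.max(np.abs(spread)) < 1e-6

    def test_max_iter_one_is_noop(self, nine_plan):
        cfg = hm.default_gs_config(max_iter=1)
        phi0 = hm.init_superposition(nine_plan, cfg)
        out = hm.wggs_optimize(nine_plan, cfg, phi0)
        assert np.array_equal(out.phase, phi0.phase)

    def test_uniformity_improves_over_init(self, nine_plan, converged_pair):
        phi0, mask = converged_pair
        rep0 = hm.mask_report(phi0, nine_plan)
        rep1 = hm.mask_report(mask, nine_plan)
        assert rep1["uniformity_rsd"] < rep0["uniformity_rsd"]
        assert rep1["uniformity_min_over_max"] > rep0["uniformity_min_over_max"]

    def test_classical_gs_mse_monotone(self, train256):
        """With one on-axis plane the loop reduces to classical GS; the
        amplitude error at the target plane is non-increasing."""
        plan = hm.plan_from_spacings([], train256, anchor=0, tile_order=[(1, 1)])
        cfg = hm.default_gs_config(max_iter=11, seed=5)
        rng = np.random.default_rng(cfg.seed)
        start = hm.PhaseMask(
            rng.uniform(0, 2 * np.pi, train256.slm_shape), train256, cfg.wavelength
        )
        mask = hm.wggs_optimize(plan, cfg, start)
        mse = [row["amplitude_mse"][0] for row in mask.provenance["log"]]
        diffs = np.diff(mse)
        assert np.all(diffs <= 1e-6)

    def test_rejects_all_zero_weights(self, train256):
        plan = hm.plan_from_spacings([], train256, anchor=0, tile_order=[(1, 1)])
        plan.planes[0].weight = 0.0
        with pytest.raises(PlanError):
            hm.wggs_optimize(plan, hm.default_gs_config())

    def test_mirrored_plan_gives_mirrored_response(self, train256):
        """Negating all dl and mirroring tiles mirrors the simulated
        response (axial and lateral symmetry of the design)."""
        cfg = hm.default_gs_config(max_iter=4)
        kwargs = dict(anchor="center", tile_shape=(3, 3))
        w = [1.0, 0.0, 1.0]  # symmetric 3-plane layout, zero order in the middle
        order = [(0, 1), (1, 1), (2, 0)]
        mirrored = [(2 - r, 2 - c) for (r, c) in order]
        plan_a = hm.plan_from_spacings([0.4, 0.4], train256,
                                       tile_order=order, weights=w, **kwargs)
        # negated dl = reversed plane order for the symmetric layout
        plan_b = hm.plan_from_spacings([0.4, 0.4], train256,
                                       tile_order=mirrored[::-1], weights=w[::-1],
                                       **kwargs)
        mask_a = hm.wggs_optimize(plan_a, cfg)
        mask_b = hm.wggs_optimize(plan_b, cfg)
        resp_a = hm.simulate_mask_response(mask_a, plan_a)
        resp_b = hm.simulate_mask_response(mask_b, plan_b)
        n_pl = len(plan_a.planes)
        for i in range(n_pl):
            ia = resp_a["intensities"][i]
            ib = resp_b["intensities"][n_pl - 1 - i]
            mirrored_ib = np.roll(np.flip(ib, axis=(0, 1)), (1, 1), axis=(0, 1))
            scale = np.max(ia)
            assert np.max(np.abs(ia - mirrored_ib)) < 1e-6 * scale


class TestQuantizePhase:
    def test_idempotent(self, converged_pair):
        _, mask = converged_pair
        q1 = hm.quantize_phase(mask, 256)
        q2 = hm.quantize_phase(q1, 256)
        assert np.array_equal(q1.phase, q2.phase)

    def test_constant_phase_snaps_to_nearest_level(self, train256):
        mask = hm.PhaseMask(np.full(train256.slm_shape, np.pi), train256, 0.55)
        q = hm.quantize_phase(mask, 8)
        ap = train256.aperture_mask()
        assert np.allclose(q.phase[ap], np.pi)  # pi is an exact 8-level value

    def test_rejects_too_few_levels(self, converged_pair):
        with pytest.raises(PlanError):
            hm.quantize_phase(converged_pair[1], 1)

    def test_256_levels_barely_change_plane_energies(self, nine_plan, converged_pair):
        _, mask = converged_pair
        q = hm.quantize_phase(mask, 256)
        e_full = np.array(hm.mask_report(mask, nine_plan)["plane_energy"])
        e_quant = np.array(hm.mask_report(q, nine_plan)["plane_energy"])
        assert np.all(np.abs(e_quant - e_full) / e_full < 0.02)


class TestMaskReport:
    def test_flat_mask_is_all_zero_order(self, nine_plan, train256):
        flat = hm.PhaseMask(np.zeros(train256.slm_shape), train256, 0.55)
        rep = hm.mask_report(flat, nine_plan)
        assert rep["zero_order_fraction"] > 0.9

    def test_converged_mask_feeds_every_tile(self, nine_plan, converged_pair):
        _, mask = converged_pair
        rep = hm.mask_report(mask, nine_plan)
        assert len(rep["plane_energy"]) == 8
        assert all(e > 0 for e in rep["plane_energy"])

    def test_crosstalk_small_for_converged_mask(self, nine_plan, converged_pair):
        _, mask = converged_pair
        rep = hm.mask_report(mask, nine_plan)
        assert rep["crosstalk_excess_fraction"] < 0.10


def test_back_propagation_pair_is_identity(train256, nine_plan):
    """Skipping the amplitude replacement, the propagate/back-propagate and
    Fourier/inverse-Fourier pairs of the plane loop compose to identity, so
    any phase is a fixed point of the replacement-free iteration."""
    cfg = hm.default_gs_config()
    rng = np.random.default_rng(0)
    tr = train256
    e0 = tr.aperture_mask() * np.exp(1j * rng.uniform(0, 2 * np.pi, tr.slm_shape))
    e_a = hm.ComplexField(e0, tr.slm_pitch, cfg.wavelength)
    e_b = hm.fourier_lens_transform(e_a, tr.f_fourier)
    for plane in nine_plan.weighted_planes()[:3]:
        e_c = hm.fresnel_propagate(e_b, plane.delta_L)
        e_e = hm.fresnel_propagate(e_c, -plane.delta_L)
        e_f = hm.fourier_lens_transform(e_e, tr.f_fourier, inverse=True)
        assert np.max(np.abs(e_f.field - e_a.field)) < 1e-8
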