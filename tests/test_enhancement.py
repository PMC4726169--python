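"""Enhancement-curve behaviour: identities, peak, baselines and folding."""

import numpy as np
import pytest
from dataclasses import replace

from goldendose.enhancement import (
    EnhancementConfig,
    default_energy_grid,
    enhancement_curve,
    fold_spectrum,
    macroscopic_enhancement,
    shell_enhancement_term,
    weight_fraction_from_uptake,
)
from goldendose.geometry import GoldShell, NucleusGeometry, mc_fraction_oracle
from goldendose.physics import electron_range, shell_weights


def test_uptake_arithmetic_gives_study_weight_fraction():
    # 500 ug/ml medium, 14-fold cellular concentration, unit density
    assert weight_fraction_from_uptake(500.0, 14.0) == pytest.approx(0.007)


class TestShellTerm:
    def test_zero_weight_fraction_kills_every_term(self, default_config):
        cfg = replace(default_config, gold_weight_fraction=0.0)
        for s in cfg.shells:
            assert shell_enhancement_term(40.0, s, cfg) == 0.0

    def test_closed_channel_below_l3_edge(self, default_config):
        l3 = next(s for s in default_config.shells if s.label == "L3")
        assert shell_enhancement_term(11.0, l3, default_config) == 0.0

    def test_term_against_independent_factor_product(self, default_config):
        """Recompute the L3 term at 40 keV from its four factors, using the
        Monte-Carlo oracle for the geometry instead of the quadrature."""
        cfg = default_config
        l3 = next(s for s in cfg.shells if s.label == "L3")
        # partition weight from first principles: cross each deeper edge
        w_partition = 1.0
        for s in cfg.shells:
            if s.binding_energy > l3.binding_energy:
                w_partition /= s.jump_ratio if 40.0 > s.binding_energy else 1.0
        w_partition *= 1.0 - 1.0 / l3.jump_ratio
        tau = w_partition * cfg.gold_photoelectric.coefficient(40.0)
        mu_w = cfg.water_reference.coefficient(40.0)
        e_e = 40.0 - l3.binding_energy
        r = electron_range(cfg.range_model, e_e)
        geom, se = mc_fraction_oracle(r, cfg.nucleus, cfg.shell, 400_000, seed=5)
        v_norm = (cfg.shell.d2**3 - cfg.shell.d1**3) / cfg.nucleus.R**3
        expected = 0.007 * (tau / mu_w) * (e_e / 40.0) * geom * v_norm
        got = shell_enhancement_term(40.0, l3, cfg)
        # MC error on the geometry factor dominates the comparison
        rel_err = 4 * se / geom
        assert got == pytest.approx(expected, rel=max(rel_err, 1e-3))


class TestCurve:
    def test_flat_unity_without_gold(self, default_config):
        cfg = replace(default_config, gold_weight_fraction=0.0)
        curve = enhancement_curve(cfg)
        assert np.all(curve.enhancement == 1.0)

    def test_enhancement_at_least_one_everywhere(self, default_config):
        curve = enhancement_curve(default_config)
        assert np.all(curve.enhancement >= 1.0)

    def test_per_shell_terms_sum_to_total(self, default_config):
        curve = enhancement_curve(default_config)
        total = 1.0 + np.sum(list(curve.per_shell_terms.values()), axis=0)
        assert np.allclose(total, curve.enhancement)

    def test_linearity_in_weight_fraction(self, default_config):
        c1 = enhancement_curve(default_config)
        c2 = enhancement_curve(
            replace(default_config, gold_weight_fraction=0.014)
        )
        assert np.allclose(c2.enhancement - 1.0, 2.0 * (c1.enhancement - 1.0))

    def test_peak_at_forty_keV_for_default_geometry(self, default_config):
        curve = enhancement_curve(default_config)
        assert curve.argmax_energy() == pytest.approx(40.0, abs=1.0)

    def test_interior_maximum_with_single_sign_change(self, default_config):
        curve = enhancement_curve(default_config)
        signs = np.sign(np.diff(curve.enhancement))
        changes = np.count_nonzero(np.diff(signs[signs != 0]))
        assert changes == 1

    def test_moving_shell_outward_never_increases_enhancement(self, default_config):
        """For a fixed amount of gold, every emission point farther from the
        nucleus means less dose: hold the gold mass (w * V_norm) fixed while
        shifting both shell radii outward."""
        near = enhancement_curve(default_config)
        far_shell = GoldShell(9.0, 19.0)
        v_near = default_config.volume_norm
        v_far = (far_shell.d2**3 - far_shell.d1**3) / default_config.nucleus.R**3
        far = enhancement_curve(
            replace(
                default_config,
                shell=far_shell,
                gold_weight_fraction=default_config.gold_weight_fraction
                * v_near / v_far,
            )
        )
        assert np.all(far.enhancement <= near.enhancement + 1e-12)

    def test_low_energy_suppression_when_range_short_of_gap(self, default_config):
        """Just-opened channels whose electrons cannot cross the nucleus-shell
        gap contribute exactly zero despite the open edge."""
        cfg = replace(default_config, shell=GoldShell(9.0, 19.0))
        l3 = next(s for s in cfg.shells if s.label == "L3")
        # at 20 keV the L3 photoelectron (~8 keV) has r ~ 1 um < d1 - R = 2 um
        e_e = 20.0 - l3.binding_energy
        assert electron_range(cfg.range_model, e_e) < cfg.shell.d1 - cfg.nucleus.R
        assert shell_enhancement_term(20.0, l3, cfg) == 0.0

    def test_auger_mode_adds_dose_at_high_energy(self, default_config):
        base = enhancement_curve(default_config)
        auger = enhancement_curve(replace(default_config, include_auger=True))
        assert np.all(auger.enhancement >= base.enhancement)
        assert auger.enhancement.max() > base.enhancement.max()

    def test_doubled_edge_grid_evaluates_both_sides(self):
        cfg = EnhancementConfig()  # default 0.5 keV grid with doubled edges
        curve = enhancement_curve(cfg)
        dup = np.flatnonzero(np.diff(curve.energies) == 0)
        assert len(dup) > 0  # edges are present twice


class TestMacroscopic:
    def test_no_gold_gives_unity(self):
        assert macroscopic_enhancement(40.0, 0.0) == pytest.approx(1.0)

    @pytest.mark.parametrize("edge", [11.9187, 13.7336, 14.3528])
    def test_upward_discontinuity_at_l_edges(self, edge):
        lo = macroscopic_enhancement(edge, 0.007, side="below")
        hi = macroscopic_enhancement(edge, 0.007, side="above")
        assert hi > lo

    def test_forty_keV_exceeds_sixty_keV(self):
        assert macroscopic_enhancement(40.0, 0.007) > macroscopic_enhancement(60.0, 0.007)


class TestFolding:
    def test_delta_spectrum_is_monoenergetic_identity(self, default_config):
        curve = enhancement_curve(default_config)
        phi = np.zeros_like(curve.energies)
        i = int(np.flatnonzero(curve.energies == 40.0)[0])
        phi[i] = 1.0
        assert fold_spectrum(curve, curve.energies, phi) == pytest.approx(
            float(curve.enhancement[i])
        )

    def test_folded_value_bracketed_by_curve_extrema(self, default_config):
        from goldendose.synthetic import SpectrumSpec, make_spectrum

        curve = enhancement_curve(default_config)
        e, phi, _ = make_spectrum(
            SpectrumSpec(160.0, 2.0, np.arange(10.0, 60.5, 0.5))
        )
        folded = fold_spectrum(curve, e, phi)
        assert curve.enhancement.min() <= folded <= curve.enhancement.max()

    def test_zero_spectrum_rejected(self, default_config):
        curve = enhancement_curve(default_config)
        with pytest.raises(ValueError):
            fold_spectrum(curve, curve.energies, np.zeros_like(curve.energies))

    def test_support_outside_curve_rejected(self, default_config):
        curve = enhancement_curve(default_config)
        with pytest.raises(ValueError):
            fold_spectrum(curve, np.array([5.0, 40.0]), np.array([1.0, 1.0]))
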