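"""Reaction-network builders: propensities, symmetries, config parsing."""

import numpy as np
import pytest

from rbfcme import (
    GeneModelParams,
    LatticeBox,
    OCSParams,
    ToggleParams,
    assemble_generator,
    build_birth_death,
    build_ocs,
    build_self_regulating_gene,
    build_toggle2d,
    build_tristable3d,
    parse_network_config,
    steady_state,
)
from rbfcme.models import ConfigError, ParameterError


class TestToggle2D:
    @pytest.mark.parametrize(
        "state, channel, expected",
        [
            ((0, 0), 0, 3e3 / 1.1e4),        # production of A at the origin
            ((0, 7), 1, 0.0),                # no A to degrade
            ((100, 100), 0, 3000.0 / (11000.0 + 100**2)),
            ((100, 100), 2, 3000.0 / (11000.0 + 100**2)),
            ((5, 40), 1, 1e-3 * 5),
            ((5, 40), 3, 1e-3 * 40),
        ],
    )
    def test_propensity_values(self, toggle_network, state, channel, expected):
        x, y = state
        got = toggle_network.channels[channel](np.array(x), np.array(y))
        assert got == pytest.approx(expected, rel=1e-12)

    def test_channel_order_and_stoichiometry(self, toggle_network):
        assert toggle_network.d == 2
        assert [ch.stoichiometry for ch in toggle_network.channels] == [
            (1, 0), (-1, 0), (0, 1), (0, -1)
        ]

    def test_formula_oracle_on_random_states(self, toggle_network, rng):
        # independent evaluation of the Hill/linear rate expressions
        states = rng.integers(0, 300, size=(50, 2))
        x, y = states[:, 0].astype(float), states[:, 1].astype(float)
        expected = [
            3e3 / (1.1e4 + y**2),
            1e-3 * x,
            3e3 / (1.1e4 + x**2),
            1e-3 * y,
        ]
        for ch, exp in zip(toggle_network.channels, expected):
            np.testing.assert_allclose(ch(x, y), exp, rtol=1e-13)

    def test_rejects_nonpositive_rates(self):
        with pytest.raises(ParameterError):
            ToggleParams(c1=-1.0, c2=1.0, c3=1.0, c4=1.0, c5=1.0, c6=1.0)
        with pytest.raises(ParameterError):
            ToggleParams(c1=1.0, c2=1.0, c3=1.0, c4=1.0, c5=1.0, c6=1.0, beta=0.5)


class TestTristable3D:
    def test_permutation_equivariance(self, rng):
        net = build_tristable3d(ToggleParams.symmetric_tristable())
        states = rng.integers(0, 300, size=(120, 3)).astype(float)
        x, y, z = states.T
        a = np.stack(net.propensities(x, y, z))  # (6, n)
        # permuting coordinates permutes the (production, degradation) pairs
        perms = [((1, 0, 2), [2, 3, 0, 1, 4, 5]),
                 ((2, 1, 0), [4, 5, 2, 3, 0, 1]),
                 ((1, 2, 0), [2, 3, 4, 5, 0, 1])]
        for coord_perm, chan_perm in perms:
            xp, yp, zp = states[:, list(coord_perm)].T
            ap = np.stack(net.propensities(xp, yp, zp))
            np.testing.assert_allclose(ap, a[chan_perm], rtol=1e-13)

    def test_origin_degradations_vanish(self):
        net = build_tristable3d(ToggleParams.symmetric_tristable())
        zero = np.array(0.0)
        for i in (1, 3, 5):
            assert net.channels[i](zero, zero, zero) == 0.0

    def test_formula_oracle(self):
        net = build_tristable3d(ToggleParams.symmetric_tristable())
        x, y, z = 50.0, 20.0, 10.0
        vals = [float(ch(np.array(x), np.array(y), np.array(z))) for ch in net.channels]
        assert vals[0] == pytest.approx(3e3 / (1.1e4 + (y + z) ** 2))
        assert vals[2] == pytest.approx(3e3 / (1.1e4 + (x + z) ** 2))
        assert vals[4] == pytest.approx(3e3 / (1.1e4 + (x + y) ** 2))
        assert vals[1::2] == pytest.approx([1e-3 * x, 1e-3 * y, 1e-3 * z])

    def test_requires_all_nine_constants(self):
        with pytest.raises(ParameterError):
            build_tristable3d(ToggleParams.symmetric_bistable())


class TestOCS:
    def test_origin_propensities_default_params(self):
        net = build_ocs(OCSParams())
        zero = np.array(0.0)
        a = [float(ch(zero, zero, zero)) for ch in net.channels]
        assert a[0] == pytest.approx(1.0)       # b_o / m_o
        assert a[2] == pytest.approx(1.0)       # b_c / m_c
        assert a[4] == pytest.approx(0.05)      # b_p / m_p = 0.5 / 10
        assert a[1] == a[3] == a[5] == 0.0

    def test_pro_osteogenic_stimulus(self):
        net = build_ocs(OCSParams(z_o=6.0))
        zero = np.array(0.0)
        assert float(net.channels[0](zero, zero, zero)) == pytest.approx(7.0)
        # stimulus touches only the osteogenic production
        base = build_ocs(OCSParams())
        x, y, z = np.array(3.0), np.array(5.0), np.array(11.0)
        for i in range(1, 6):
            assert float(net.channels[i](x, y, z)) == pytest.approx(
                float(base.channels[i](x, y, z))
            )

    def test_inflection_point_touches_only_progenitor_production(self):
        a = build_ocs(OCSParams(m_p=10.0))
        b = build_ocs(OCSParams(m_p=8.0))
        x, y, z = np.array(4.0), np.array(6.0), np.array(9.0)
        for i in range(6):
            va, vb = float(a.channels[i](x, y, z)), float(b.channels[i](x, y, z))
            if i == 4:
                assert va != pytest.approx(vb)
            else:
                assert va == pytest.approx(vb)

    def test_osteo_chondro_swap_equivariance(self, rng):
        net = build_ocs(OCSParams())
        states = rng.integers(0, 60, size=(100, 3)).astype(float)
        x, y, z = states.T
        a = np.stack(net.propensities(x, y, z))
        a_sw = np.stack(net.propensities(y, x, z))
        np.testing.assert_allclose(a_sw, a[[2, 3, 0, 1, 4, 5]], rtol=1e-13)


class TestSelfRegulatingGene:
    def test_binding_rates(self):
        mono = GeneModelParams(g_on=10, g_off=1, k=1, f=1, h=2, binding_mode="monomer")
        dim = GeneModelParams(g_on=10, g_off=1, k=1, f=1, h=2, binding_mode="dimer")
        assert mono.h_of_x(3) == pytest.approx(6.0)
        assert dim.h_of_x(1) == pytest.approx(0.0)
        assert dim.h_of_x(4) == pytest.approx(12.0)

    def test_unitless_parameters(self):
        p = GeneModelParams(g_on=30, g_off=10, k=2, f=6, h=3)
        assert p.X_ad == pytest.approx(10.0)
        assert p.X_eq == pytest.approx(2.0)
        assert p.omega == pytest.approx(3.0)

    def test_invalid_binding_mode(self):
        with pytest.raises(ParameterError):
            GeneModelParams(g_on=1, g_off=1, k=1, f=1, h=1, binding_mode="trimer")

    def test_generator_conserves_and_off0_unreachable(self):
        p = GeneModelParams(g_on=20, g_off=2, k=1, f=0.5, h=0.05)
        net = build_self_regulating_gene(p)
        box = LatticeBox((0, 0), (80, 1))
        gen = assemble_generator(net, box)
        colsums = np.asarray(gen.matrix.sum(axis=0)).ravel()
        assert np.abs(colsums).max() < 1e-12
        ss = steady_state(gen)
        g = ss.grid_values()
        # the bound state always carries at least the bound repressor
        assert g[0, 1] < 1e-15

    @pytest.mark.parametrize("mode", ["monomer", "dimer"])
    def test_peak_fusion_with_fast_switching(self, mode):
        """Slow on/off switching gives a bimodal protein distribution, fast
        switching fuses the peaks (full-grid steady state as oracle)."""

        def n_modes(f, h):
            p = GeneModelParams(g_on=60.0, g_off=2.0, k=1.0, f=f, h=h, binding_mode=mode)
            net = build_self_regulating_gene(p)
            box = LatticeBox((0, 0), (120, 1))
            ss = steady_state(assemble_generator(net, box))
            tot = ss.grid_values().sum(axis=1)
            floor = 1e-6 * tot.max()
            return sum(
                1
                for i in range(1, 120)
                if tot[i] > max(tot[i - 1], floor) and tot[i] >= tot[i + 1]
            )

        slow = n_modes(0.05, 0.002 if mode == "monomer" else 1e-4)
        fast = n_modes(50.0, 2.0 if mode == "monomer" else 0.1)
        assert slow >= 2
        assert fast == 1


class TestConfigParsing:
    def test_builtin_round_trip(self, tmp_path, toggle_network, rng):
        cfg = tmp_path / "toggle.yaml"
        cfg.write_text(
            "model: toggle2d\n"
            "params: {c1: 3.0e3, c2: 1.1e4, c3: 1.0e-3, c4: 3.0e3, c5: 1.1e4, c6: 1.0e-3}\n"
        )
        net = parse_network_config(cfg)
        states = rng.integers(0, 200, size=(20, 2)).astype(float)
        for ch_a, ch_b in zip(net.channels, toggle_network.channels):
            assert ch_a.stoichiometry == ch_b.stoichiometry
            np.testing.assert_allclose(
                ch_a(states[:, 0], states[:, 1]), ch_b(states[:, 0], states[:, 1])
            )

    def test_negative_rate_rejected(self, tmp_path):
        cfg = tmp_path / "bad.yaml"
        cfg.write_text("model: birth_death\nparams: {lam: -5.0, mu: 1.0}\n")
        with pytest.raises(ConfigError):
            parse_network_config(cfg)

    def test_custom_birth_death_matches_tridiagonal_oracle(self, tmp_path):
        lam, mu, N = 4.0, 0.5, 12
        cfg = tmp_path / "bd.yaml"
        cfg.write_text(
            "model: custom\nd: 1\nparams: {lam: 4.0, mu: 0.5}\n"
            "channels:\n"
            "  - {shift: [1], propensity: 'lam'}\n"
            "  - {shift: [-1], propensity: 'mu * x1'}\n"
        )
        net = parse_network_config(cfg)
        box = LatticeBox((0,), (N,))
        L = assemble_generator(net, box).matrix.toarray()
        # hand-written tri-diagonal generator with conserving truncation
        oracle = np.zeros((N + 1, N + 1))
        for x in range(N + 1):
            if x < N:
                oracle[x + 1, x] += lam
                oracle[x, x] -= lam
            if x > 0:
                oracle[x - 1, x] += mu * x
                oracle[x, x] -= mu * x
        np.testing.assert_allclose(L, oracle, atol=1e-14)

    def test_unsafe_expression_rejected(self, tmp_path):
        cfg = tmp_path / "evil.yaml"
        cfg.write_text(
            "model: custom\nd: 1\n"
            "channels:\n"
            "  - {shift: [1], propensity: '__import__(\"os\").getpid()'}\n"
        )
        with pytest.raises(ConfigError):
            parse_network_config(cfg)

    def test_unknown_model(self, tmp_path):
        cfg = tmp_path / "x.yaml"
        cfg.write_text("model: nosuchthing\n")
        with pytest.raises(ConfigError):
            parse_network_config(cfg)

    def test_missing_file(self, tmp_path):
        with pytest.raises(ConfigError):
            parse_network_config(tmp_path / "absent.yaml")


def test_propensities_nonnegative_on_boxes(rng):
    """All built-in models have non-negative propensities on their boxes."""
    nets = [
        build_toggle2d(ToggleParams.symmetric_bistable()),
        build_tristable3d(ToggleParams.symmetric_tristable()),
        build_tristable3d(ToggleParams.scaled_tristable()),
        build_ocs(OCSParams()),
        build_self_regulating_gene(GeneModelParams(g_on=20, g_off=2, k=1, f=1, h=0.1)),
        build_birth_death(3.0, 0.7),
    ]
    for net in nets:
        states = rng.integers(0, 120, size=(200, net.d)).astype(float)
        if net.components is not None:
            states[:, net.component_axis] = rng.integers(0, 2, size=200)
        for ch in net.channels:
            assert np.all(ch(*states.T) >= 0), (net.name, ch.name)
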