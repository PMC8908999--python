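"""Stick-zeppelin-ball signal model: closed forms, symmetries, noise."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from peridmi.forward_model import (
    AcquisitionScheme,
    MicrostructureParams,
    ValidationError,
    add_rician_noise,
    compartment_signal,
    default_scheme,
    spherical_mean,
    voxel_signal,
)
from conftest import sphere_points

Z = np.array([0.0, 0.0, 1.0])
X = np.array([1.0, 0.0, 0.0])


def params(v=(1 / 3, 1 / 3, 1 / 3), **kw):
    return MicrostructureParams(v_i=v[0], v_e=v[1], v_f=v[2], **kw)


class TestCompartmentSignal:
    def test_zero_b_gives_unit_attenuation(self):
        assert compartment_signal(params(), 0.0, Z) == (1.0, 1.0, 1.0)

    def test_ball_closed_form(self):
        _, _, free = compartment_signal(params(D_f=3.0), 1.0, X)
        assert free == pytest.approx(np.exp(-3.0), abs=1e-12)

    def test_stick_parallel_perpendicular(self):
        p = params(D_i=2.0, orientation=Z)
        intra_perp, _, _ = compartment_signal(p, 1.0, X)
        intra_par, _, _ = compartment_signal(p, 1.0, Z)
        assert intra_perp == pytest.approx(1.0, abs=1e-12)
        assert intra_par == pytest.approx(np.exp(-2.0), abs=1e-12)

    def test_rejects_negative_b_and_non_unit_direction(self):
        with pytest.raises(ValidationError):
            compartment_signal(params(), -0.5, Z)
        with pytest.raises(ValidationError):
            compartment_signal(params(), 1.0, np.array([0.0, 0.0, 2.0]))


class TestVoxelSignal:
    def test_pure_free_water_collapse(self, scheme):
        p = params((0.0, 0.0, 1.0), D_f=3.0, s0=2.5)
        sig = voxel_signal(p, scheme)
        expected = 2.5 * np.exp(-3.0 * scheme.bvalues)
        np.testing.assert_allclose(sig, expected, atol=1e-12)

    def test_b0_equals_s0(self, scheme, canonical_voxel):
        sig = voxel_signal(canonical_voxel, scheme)
        np.testing.assert_allclose(sig[scheme.b0_mask], canonical_voxel.s0)

    def test_signal_non_increasing_in_b(self):
        g = Z
        p = params((0.3, 0.5, 0.2), orientation=sphere_points(1, 3)[0])
        atten = [
            sum(f * c for f, c in zip(p.fractions, compartment_signal(p, b, g)))
            for b in (0.0, 1.0, 2.0)
        ]
        assert atten[0] >= atten[1] >= atten[2]

    def test_rotation_invariance(self, scheme):
        """Joint rotation of fiber and gradients leaves the signal unchanged."""
        from scipy.spatial.transform import Rotation

        rng = np.random.default_rng(11)
        for _ in range(5):
            R = Rotation.random(rng=rng).as_matrix()
            u = sphere_points(1, 7)[0]
            p = params((0.5, 0.3, 0.2), orientation=u)
            p_rot = params((0.5, 0.3, 0.2), orientation=R @ u)
            rot_scheme = AcquisitionScheme(
                scheme.bvalues, scheme.directions @ R.T, scheme.shell_tolerance
            )
            np.testing.assert_allclose(
                voxel_signal(p, scheme), voxel_signal(p_rot, rot_scheme), atol=1e-10
            )

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(
        w=st.tuples(*[st.floats(0.01, 1.0)] * 3),
        t=st.floats(0.0, 1.0),
    )
    def test_linearity_in_fractions(self, scheme, w, t):
        """The voxel signal is linear in (v_i, v_e, v_f) at fixed diffusivities."""
        a = np.array(w) / sum(w)
        b = np.array([0.2, 0.3, 0.5])
        mix = t * a + (1 - t) * b
        sigs = [
            voxel_signal(params(tuple(v)), scheme) for v in (a, b, mix)
        ]
        np.testing.assert_allclose(t * sigs[0] + (1 - t) * sigs[1], sigs[2], atol=1e-12)


class TestSphericalMean:
    def test_stick_mean_against_quadrature(self):
        p = params(D_i=2.0)
        g = sphere_points(100_000, 1)
        quad = np.mean(np.exp(-1.0 * 2.0 * (g @ p.orientation) ** 2))
        stick, _, _ = spherical_mean(p, 1.0)
        assert stick == pytest.approx(quad, abs=2e-3)
        assert stick == pytest.approx(0.598, abs=1e-3)

    def test_isotropic_zeppelin_limit(self):
        p = params(D_e_par=1.0, D_e_perp=1.0)
        _, extra, _ = spherical_mean(p, 1.0)
        assert extra == pytest.approx(np.exp(-1.0), abs=1e-9)

    def test_zeppelin_limit_is_continuous(self):
        near = params(D_e_par=1.0 + 5e-7, D_e_perp=1.0)
        exact = params(D_e_par=1.0, D_e_perp=1.0)
        assert spherical_mean(near, 1.0)[1] == pytest.approx(
            spherical_mean(exact, 1.0)[1], abs=1e-6
        )

    def test_ball_is_its_own_mean(self):
        _, _, free = spherical_mean(params(D_f=3.0), 1.0)
        assert free == pytest.approx(np.exp(-3.0), abs=1e-12)

    def test_rejects_nonpositive_b(self):
        with pytest.raises(ValidationError):
            spherical_mean(params(), 0.0)

    @pytest.mark.parametrize("b", [0.5, 1.0, 2.0, 3.0])
    @pytest.mark.parametrize("D_i,D_e_par,D_e_perp", [
        (0.1, 0.1, 0.05), (1.0, 0.8, 0.3), (2.0, 1.5, 0.5), (3.0, 3.0, 1.0),
    ])
    def test_closed_forms_match_quadrature_grid(self, b, D_i, D_e_par, D_e_perp):
        """Analytic powder averages vs 2e4-direction numerical averaging."""
        p = params(D_i=D_i, D_e_par=D_e_par, D_e_perp=D_e_perp)
        g = sphere_points(20_000, 5)
        cos2 = (g @ p.orientation) ** 2
        stick_q = np.mean(np.exp(-b * D_i * cos2))
        extra_q = np.mean(np.exp(-b * (D_e_perp + (D_e_par - D_e_perp) * cos2)))
        stick, extra, _ = spherical_mean(p, b)
        # Monte-Carlo quadrature error at 2e4 points is a few 1e-3
        assert stick == pytest.approx(stick_q, abs=5e-3)
        assert extra == pytest.approx(extra_q, abs=5e-3)

    def test_powder_average_of_voxel_signal(self, canonical_voxel):
        """Dense one-shell powder average = fraction-weighted spherical means."""
        g = sphere_points(4000, 9)
        b = 1.0
        intra, extra, free = compartment_signal(canonical_voxel, b, g)
        powder = np.mean(
            canonical_voxel.v_i * intra
            + canonical_voxel.v_e * extra
            + canonical_voxel.v_f * free
        )
        sm = spherical_mean(canonical_voxel, b)
        expected = float(np.dot(canonical_voxel.fractions, sm))
        assert powder == pytest.approx(expected, abs=1e-2)


class TestRicianNoise:
    def test_zero_sigma_is_identity(self):
        sig = np.linspace(0.1, 1.0, 10)
        np.testing.assert_array_equal(add_rician_noise(sig, 0.0, 1), sig)

    def test_deterministic_given_seed(self):
        sig = np.ones(100)
        np.testing.assert_array_equal(
            add_rician_noise(sig, 0.05, 42), add_rician_noise(sig, 0.05, 42)
        )

    def test_second_moment_of_rice(self):
        """E[S_noisy^2] = S^2 + 2 sigma^2 for Rician corruption."""
        sig = np.ones(100_000)
        noisy = add_rician_noise(sig, 0.05, 7)
        assert np.mean(noisy**2) == pytest.approx(1.0 + 2 * 0.05**2, abs=1e-3)

    def test_rejects_negative_sigma(self):
        with pytest.raises(ValidationError):
            add_rician_noise(np.ones(3), -0.1, 0)


class TestAcquisitionScheme:
    def test_default_scheme_structure(self, scheme):
        np.testing.assert_allclose(scheme.shells, [1.0, 2.0])
        assert scheme.b0_mask.sum() == 1
        assert scheme.n_volumes == 61
        norms = np.linalg.norm(scheme.directions[~scheme.b0_mask], axis=1)
        np.testing.assert_allclose(norms, 1.0, atol=1e-9)

    def test_requires_b0_and_two_shells(self):
        g = sphere_points(4, 0)
        with pytest.raises(ValidationError, match="b=0"):
            AcquisitionScheme(np.array([1.0, 1.0, 2.0, 2.0]), g)
        with pytest.raises(ValidationError, match="shells"):
            AcquisitionScheme(
                np.array([0.0, 1.0, 1.0, 1.0]), np.vstack([[0, 0, 0], g[:3]])
            )

    def test_rejects_non_unit_dw_direction(self):
        dirs = np.array([[0, 0, 0], [0, 0, 2.0], [1, 0, 0]], dtype=float)
        with pytest.raises(ValidationError, match="unit"):
            AcquisitionScheme(np.array([0.0, 1.0, 2.0]), dirs)

    def test_repulsion_directions_cover_sphere(self, scheme):
        """Powder average of a stick over the default 30-direction shell is
        close to the analytic spherical mean (direction-set quality)."""
        p = params(D_i=2.0, orientation=sphere_points(1, 13)[0])
        shell = scheme.directions[np.abs(scheme.bvalues - 1.0) < 0.05]
        quad = np.mean(np.exp(-2.0 * (shell @ p.orientation) ** 2))
        assert quad == pytest.approx(spherical_mean(p, 1.0)[0], abs=5e-3)
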