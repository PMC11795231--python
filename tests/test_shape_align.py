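"""GPA, semilandmark sliding, and tangent projection."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dentasym import (
    DigitizedConfiguration,
    bending_energy,
    bending_energy_matrix,
    center_and_scale,
    gpa,
    procrustes_distance,
    project_to_tangent,
)
from dentasym.errors import DegenerateConfigurationError
from dentasym.shape_align import slide_configuration
from dentasym.synthetic_data import mean_template


def _cfg(coords, ind="a", side="L", rep=1):
    k = len(coords)
    return DigitizedConfiguration(ind, "BG", "UM1", side, rep, np.asarray(coords, float))


def _rot(theta):
    c, s = np.cos(theta), np.sin(theta)
    return np.array([[c, s], [-s, c]])


class TestCenterAndScale:
    def test_offset_unit_square_is_centred_with_unit_size(self):
        square = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], float) + [5, 7]
        out = center_and_scale(_cfg(square))
        np.testing.assert_allclose(out.coords.mean(0), 0, atol=1e-15)
        assert np.sqrt((out.coords**2).sum()) == pytest.approx(1.0)
        assert out.centroid_size == pytest.approx(np.sqrt(4 * 0.5))

    def test_scale_invariance(self):
        tri = np.array([[0, 0], [4, 0], [0, 3]], float)
        a = center_and_scale(_cfg(tri))
        b = center_and_scale(_cfg(tri * 10))
        np.testing.assert_allclose(a.coords, b.coords, atol=1e-14)

    def test_centroid_size_closed_form_on_345_triangle(self):
        tri = np.array([[0, 0], [4, 0], [0, 3]], float)
        centred = tri - tri.mean(0)
        assert center_and_scale(_cfg(tri)).centroid_size == pytest.approx(
            np.sqrt((centred**2).sum())
        )

    def test_coincident_points_rejected(self):
        with pytest.raises(DegenerateConfigurationError):
            center_and_scale(_cfg(np.ones((5, 2))))


class TestGPA:
    def test_similarity_copies_align_exactly(self, rng):
        base = rng.normal(size=(6, 2))
        configs = []
        for i in range(5):
            xf = base @ _rot(rng.uniform(0, 2 * np.pi)) * rng.uniform(0.5, 3) + rng.normal(size=2)
            configs.append(_cfg(xf, ind=f"i{i}"))
        res = gpa(configs)
        assert res.converged
        stack = np.stack([a.coords for a in res.aligned])
        for i in range(5):
            for j in range(i + 1, 5):
                assert np.linalg.norm(stack[i] - stack[j]) < 1e-8
        assert procrustes_distance(res.mean_shape, base) < 1e-8

    def test_two_shape_distance_matches_rotation_grid_oracle(self, rng):
        a, b = rng.normal(size=(2, 5, 2))
        res = gpa([_cfg(a), _cfg(b, ind="b")])
        ours = np.linalg.norm(res.aligned[0].coords - res.aligned[1].coords)
        # oracle: dense minimisation over the rotation angle
        aa = a - a.mean(0); aa /= np.sqrt((aa**2).sum())
        bb = b - b.mean(0); bb /= np.sqrt((bb**2).sum())
        thetas = np.linspace(0, 2 * np.pi, 400001)
        best = min(
            np.linalg.norm(aa @ _rot(t) - bb) for t in thetas
        )
        assert ours == pytest.approx(best, abs=1e-6)

    def test_input_order_does_not_change_alignment(self, rng):
        configs = [_cfg(rng.normal(size=(6, 2)), ind=f"i{i}") for i in range(6)]
        res1 = gpa(configs)
        res2 = gpa(configs[::-1])
        by_id1 = {a.individual_id: a.coords for a in res1.aligned}
        by_id2 = {a.individual_id: a.coords for a in res2.aligned}
        for k in by_id1:
            # both runs may differ by one global rotation; compare shapes
            assert procrustes_distance(by_id1[k], by_id2[k]) < 1e-8

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(
        theta=st.floats(0, 2 * np.pi),
        scale=st.floats(0.1, 10),
        dx=st.floats(-50, 50),
        dy=st.floats(-50, 50),
    )
    def test_similarity_invariance_property(self, theta, scale, dx, dy):
        """Transforming one input configuration by any similarity leaves
        the GPA solution unchanged (to 1e-8)."""
        rng = np.random.default_rng(42)
        shapes = [rng.normal(size=(6, 2)) for _ in range(4)]
        base = gpa([_cfg(s, ind=f"i{i}") for i, s in enumerate(shapes)])
        shapes2 = [s.copy() for s in shapes]
        shapes2[2] = shapes2[2] @ _rot(theta) * scale + [dx, dy]
        alt = gpa([_cfg(s, ind=f"i{i}") for i, s in enumerate(shapes2)])
        for a, b in zip(base.aligned, alt.aligned):
            assert procrustes_distance(a.coords, b.coords) < 1e-8


class TestSliding:
    def test_reference_outline_is_a_fixed_point(self, um1_scheme, um1_template):
        bem = bending_energy_matrix(um1_template)
        out = slide_configuration(um1_template.copy(), um1_scheme, bem)
        np.testing.assert_allclose(out, um1_template, atol=1e-12)

    def test_single_perturbation_matches_dense_grid_search(self, um1_scheme, um1_template):
        """Sliding one perturbed semilandmark lands where a dense 1-D search
        along its tangent says the bending energy is minimal."""
        bem = bending_energy_matrix(um1_template)
        cfg = um1_template.copy()
        j = um1_scheme.n_fixed + 7
        cfg[j] += [0.03, -0.01]
        before = bending_energy(cfg, bem)
        out = slide_configuration(cfg, um1_scheme, bem)
        after = bending_energy(out, bem)
        assert after <= before

        # grid-search oracle: slide only point j along its own tangent
        semis = um1_scheme.semi_indices
        pts = cfg[semis]
        local = j - um1_scheme.n_fixed
        chord = pts[(local + 1) % 20] - pts[(local - 1) % 20]
        u = chord / np.linalg.norm(chord)
        ts = np.linspace(-0.1, 0.1, 20001)
        energies = []
        for t in ts:
            trial = cfg.copy()
            trial[j] += t * u
            energies.append(bending_energy(trial, bem))
        best = min(energies)
        # full sliding moves all 20 semilandmarks, so it can only do better
        assert after <= best + 1e-12

    def test_fixed_landmarks_never_move(self, um1_scheme, um1_template, rng):
        bem = bending_energy_matrix(um1_template)
        cfg = um1_template + rng.normal(0, 0.01, size=um1_template.shape)
        out = slide_configuration(cfg.copy(), um1_scheme, bem)
        np.testing.assert_array_equal(out[: um1_scheme.n_fixed], cfg[: um1_scheme.n_fixed])

    def test_energy_monotone_over_sweeps_and_reaches_fixed_point(
        self, um1_scheme, um1_template, rng
    ):
        bem = bending_energy_matrix(um1_template)
        # perturbation at the scale of realistic digitizing + shape noise
        cfg = um1_template + rng.normal(0, 0.005, size=um1_template.shape)
        energies = [bending_energy(cfg, bem)]
        cur = cfg.copy()
        for _ in range(5):
            cur = slide_configuration(cur, um1_scheme, bem)
            energies.append(bending_energy(cur, bem))
        assert all(b <= a + 1e-12 for a, b in zip(energies, energies[1:]))
        # well-separated outline: five sweeps suffice for a fixed point
        final = slide_configuration(cur, um1_scheme, bem)
        assert np.abs(final - cur).max() < 1e-4


class TestTangentProjection:
    def test_mean_projects_to_itself(self, um1_template):
        mu = um1_template.ravel()
        out = project_to_tangent(um1_template, um1_template)
        np.testing.assert_allclose(out.vector, mu / np.linalg.norm(mu), atol=1e-12)

    def test_projection_is_idempotent(self, um1_template, rng):
        x = um1_template + rng.normal(0, 0.01, um1_template.shape)
        x -= x.mean(0)
        x /= np.sqrt((x**2).sum())
        once = project_to_tangent(x, um1_template).vector
        twice = project_to_tangent(once.reshape(-1, 2), um1_template).vector
        np.testing.assert_allclose(twice, once, atol=1e-12)

    def test_small_shape_differences_preserve_procrustes_distance(self, um1_template, rng):
        from dentasym.shape_align import optimal_rotation

        mu = um1_template
        for _ in range(5):
            x = mu + rng.normal(0, 0.005, mu.shape)
            x = x - x.mean(0)
            x /= np.sqrt((x**2).sum())
            x = x @ optimal_rotation(x, mu)  # as after GPA alignment
            rho = procrustes_distance(x, mu)
            t = project_to_tangent(x, mu).vector - project_to_tangent(mu, mu).vector
            assert rho < 0.05
            assert abs(np.linalg.norm(t) - rho) / rho < 0.01
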