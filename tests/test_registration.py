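"""Kernel deformation, varifold dissimilarity and registration descent."""

import numpy as np
import pytest

import fshapems.registration as R
from fshapems.meshing import FShape, TriMesh, mesh_in_mm
from fshapems.registration import (
    RegistrationConfig,
    RegistrationParams,
    deform,
    estimate_atlas,
    evaluate_objective,
    fvarifold_dissimilarity,
    gaussian_gram,
    geodesic_energy,
    register_subject,
)

from conftest import tiny_fshape


def single_vertex_mesh():
    return TriMesh(
        np.zeros((1, 3)), np.empty((0, 3), dtype=int), np.zeros((1, 2), dtype=int), 1.0
    )


def brute_force_dissimilarity(a: FShape, b: FShape, cfg: RegistrationConfig) -> float:
    """Independent double-sum oracle over face pairs, written as plain loops."""

    def face_quantities(fs):
        v = mesh_in_mm(fs.mesh)
        out = []
        for tri in fs.mesh.faces:
            p1, p2, p3 = v[tri[0]], v[tri[1]], v[tri[2]]
            n = np.cross(p2 - p1, p3 - p1)
            area = np.linalg.norm(n) / 2.0
            if area <= 1e-14:
                continue
            out.append(((p1 + p2 + p3) / 3.0, n / np.linalg.norm(n), area,
                        (fs.signal[tri[0]] + fs.signal[tri[1]] + fs.signal[tri[2]]) / 3.0))
        return out

    def inner(fa, fb):
        tot = 0.0
        for c1, n1, a1, s1 in fa:
            for c2, n2, a2, s2 in fb:
                tot += (
                    np.exp(-np.sum((c1 - c2) ** 2) / cfg.sigma_W**2)
                    * np.dot(n1, n2) ** 2
                    * np.exp(-((s1 - s2) ** 2) / cfg.sigma_sig**2)
                    * a1
                    * a2
                )
        return tot

    qa, qb = face_quantities(a), face_quantities(b)
    return inner(qa, qa) - 2 * inner(qa, qb) + inner(qb, qb)


class TestGaussianGram:
    def test_coincident_points_give_ones(self):
        G = gaussian_gram(np.zeros((2, 3)), 1.0)
        np.testing.assert_allclose(G, np.ones((2, 2)))

    def test_distant_points_decorrelate(self):
        pts = np.array([[0.0, 0, 0], [100.0, 0, 0]])
        G = gaussian_gram(pts, 1.0)
        assert G[0, 1] < 1e-300 or G[0, 1] == 0.0

    @pytest.mark.parametrize("seed", range(5))
    def test_positive_semidefinite(self, seed):
        pts = np.random.default_rng(seed).normal(size=(12, 3))
        G = gaussian_gram(pts, 0.7)
        assert np.linalg.eigvalsh(G).min() >= -1e-10

    def test_invalid_sigma(self):
        with pytest.raises(ValueError):
            gaussian_gram(np.zeros((2, 3)), 0.0)


class TestDeform:
    def test_zero_momenta_is_identity(self, small_fshape):
        cfg = RegistrationConfig()
        out = deform(small_fshape.mesh, np.zeros((small_fshape.mesh.n_vertices, 3)), cfg)
        np.testing.assert_array_equal(out.vertices, small_fshape.mesh.vertices)

    def test_single_vertex_unit_momentum_translates_by_one(self):
        # one Euler step: x1 = x0 + h·K(x0,x0)·p = 0 + 1·1·(1,0,0)
        cfg = RegistrationConfig(shoot_steps=1, sigma_V=1.0)
        mesh = single_vertex_mesh()
        out = deform(mesh, np.array([[1.0, 0.0, 0.0]]), cfg)
        np.testing.assert_allclose(out.vertices[0], [1.0, 0.0, 0.0])

    def test_wide_kernel_limit_is_rigid_translation(self, small_fshape):
        cfg = RegistrationConfig(sigma_V=1e6)
        n = small_fshape.mesh.n_vertices
        p = np.tile([0.3 / n, 0.1 / n, 0.0], (n, 1))
        out = deform(small_fshape.mesh, p, cfg)
        disp = mesh_in_mm(out) - mesh_in_mm(small_fshape.mesh)
        assert np.allclose(disp, disp[0], atol=1e-9)
        np.testing.assert_allclose(disp[0], [0.3, 0.1, 0.0], atol=1e-9)


class TestGeodesicEnergy:
    def test_zero_momenta_zero_energy(self, small_fshape):
        cfg = RegistrationConfig()
        V = small_fshape.mesh.n_vertices
        assert geodesic_energy(small_fshape.mesh, np.zeros((V, 3)), cfg) == 0.0

    def test_single_vertex_energy_is_p_squared(self):
        cfg = RegistrationConfig(sigma_V=1.0)
        assert geodesic_energy(single_vertex_mesh(), np.array([[2.0, 0, 0]]), cfg) == 4.0

    def test_quadratic_in_momenta(self, small_fshape):
        cfg = RegistrationConfig()
        rng = np.random.default_rng(0)
        p = rng.normal(size=(small_fshape.mesh.n_vertices, 3))
        e1 = geodesic_energy(small_fshape.mesh, p, cfg)
        e2 = geodesic_energy(small_fshape.mesh, 2 * p, cfg)
        assert e2 == pytest.approx(4 * e1)


class TestVarifold:
    def test_self_dissimilarity_zero(self, small_fshape):
        cfg = RegistrationConfig()
        assert fvarifold_dissimilarity(small_fshape, small_fshape, cfg) == 0.0

    def test_symmetry(self):
        cfg = RegistrationConfig(sigma_W=0.8, sigma_sig=12.0)
        a, b = tiny_fshape(1), tiny_fshape(2)
        assert fvarifold_dissimilarity(a, b, cfg) == pytest.approx(
            fvarifold_dissimilarity(b, a, cfg), rel=1e-12
        )

    def test_single_triangle_signal_offset_closed_form(self):
        verts = np.array([[0.0, 0, 0], [2.0, 0, 0], [0.0, 2, 0]])
        faces = np.array([[0, 1, 2]])
        lat = np.zeros((3, 2), dtype=int)
        delta = 7.0
        cfg = RegistrationConfig(sigma_sig=20.0)
        a = FShape(TriMesh(verts, faces, lat, 1.0), np.full(3, 50.0))
        b = FShape(TriMesh(verts.copy(), faces.copy(), lat, 1.0), np.full(3, 50.0 + delta))
        area = 2.0  # legs 2 mm; z is µm so the projected area is exact
        expect = 2 * area**2 * (1 - np.exp(-(delta**2) / cfg.sigma_sig**2))
        assert fvarifold_dissimilarity(a, b, cfg) == pytest.approx(expect, rel=1e-12)

    @pytest.mark.parametrize("seed", [3, 4, 5])
    def test_matches_brute_force_oracle(self, seed):
        cfg = RegistrationConfig(sigma_W=0.9, sigma_sig=15.0)
        a = tiny_fshape(seed, n=3)  # 18 faces
        b = tiny_fshape(seed + 100, n=3)
        got = fvarifold_dissimilarity(a, b, cfg)
        want = brute_force_dissimilarity(a, b, cfg)
        assert got == pytest.approx(want, rel=1e-10)

    def test_degenerate_face_skipped_with_warning(self):
        verts = np.array([[0.0, 0, 0], [1.0, 0, 0], [2.0, 0, 0], [0.0, 1, 0]])
        faces = np.array([[0, 1, 2], [0, 1, 3]])  # first face has zero area
        lat = np.zeros((4, 2), dtype=int)
        fs = FShape(TriMesh(verts, faces, lat, 1.0), np.zeros(4))
        cfg = RegistrationConfig()
        with pytest.warns(RuntimeWarning, match="zero-area"):
            assert fvarifold_dissimilarity(fs, fs, cfg) == 0.0


class TestAdjoints:
    """Hand-derived reverse-mode gradients against central finite differences."""

    def _fd(self, f, x, eps=1e-6):
        g = np.zeros_like(x)
        it = np.nditer(x, flags=["multi_index"])
        for _ in it:
            i = it.multi_index
            xp, xm = x.copy(), x.copy()
            xp[i] += eps
            xm[i] -= eps
            g[i] = (f(xp) - f(xm)) / (2 * eps)
        return g

    def test_shooting_adjoint(self):
        rng = np.random.default_rng(0)
        sigma, steps = 0.8, 4
        x0 = rng.normal(size=(6, 3))
        p0 = 0.3 * rng.normal(size=(6, 3))
        w = rng.normal(size=(6, 3))

        def loss(x, p):
            return float(np.sum(w * R._shoot(x, p, sigma, steps)[-1][0]))

        traj = R._shoot(x0, p0, sigma, steps)
        bx, bp = R._shoot_vjp(traj, w, sigma, steps)
        np.testing.assert_allclose(bx, self._fd(lambda x: loss(x, p0), x0), atol=1e-7)
        np.testing.assert_allclose(bp, self._fd(lambda p: loss(x0, p), p0), atol=1e-7)

    def test_varifold_gradient(self):
        rng = np.random.default_rng(1)
        cfg = RegistrationConfig(sigma_W=0.6, sigma_sig=9.0)
        faces = np.array([[0, 1, 2], [1, 3, 2], [2, 3, 4]])
        va = rng.normal(size=(5, 3))
        sa = 5 * rng.normal(size=5)
        vb = 1.1 * rng.normal(size=(5, 3))
        sb = 5 * rng.normal(size=5)
        B = R._FaceGeom(vb, faces)
        fb = B.fbar(sb)

        def inner(v, s):
            A = R._FaceGeom(v, faces)
            return R._vf_inner(A, A.fbar(s), B, fb, cfg)

        A = R._FaceGeom(va, faces)
        gv, gs = R._vf_inner_grad(A, A.fbar(sa), B, fb, cfg)
        np.testing.assert_allclose(gv, self._fd(lambda v: inner(v, sa), va), atol=1e-7)
        np.testing.assert_allclose(gs, self._fd(lambda s: inner(va, s), sa), atol=1e-7)


class TestObjective:
    def test_global_minimum_is_zero(self, small_fshape):
        cfg = RegistrationConfig()
        zero_t = FShape(small_fshape.mesh, np.zeros(small_fshape.mesh.n_vertices))
        params = [RegistrationParams.zeros(zero_t.mesh.n_vertices)]
        J, terms = evaluate_objective(zero_t, [zero_t], params, cfg)
        assert J == 0.0

    def test_zero_params_decompose_into_signal_and_dissimilarity(self):
        cfg = RegistrationConfig()
        template = tiny_fshape(0, n=2)
        subjects = [tiny_fshape(7, n=2), tiny_fshape(8, n=2)]
        params = [RegistrationParams.zeros(template.mesh.n_vertices) for _ in subjects]
        J, terms = evaluate_objective(template, subjects, params, cfg)
        from fshapems.meshing import vertex_area_weights

        w = vertex_area_weights(mesh_in_mm(template.mesh), template.mesh.faces)
        expect_f = cfg.gamma_f * float(np.sum(template.signal**2 * w))
        expect_A = sum(cfg.gamma_w * fvarifold_dissimilarity(template, s, cfg) for s in subjects)
        assert terms["geodesic"] == 0.0 and terms["zeta"] == 0.0
        assert terms["template_signal"] == pytest.approx(expect_f, rel=1e-9)
        assert terms["dissimilarity"] == pytest.approx(expect_A, rel=1e-9)
        assert J == pytest.approx(expect_f + expect_A, rel=1e-9)

    def test_gamma_w_scales_only_dissimilarity(self):
        template, subject = tiny_fshape(0, n=2), tiny_fshape(9, n=2)
        params = [RegistrationParams.zeros(template.mesh.n_vertices)]
        _, t1 = evaluate_objective(template, [subject], params, RegistrationConfig(gamma_w=1.0))
        _, t2 = evaluate_objective(template, [subject], params, RegistrationConfig(gamma_w=3.0))
        assert t2["dissimilarity"] == pytest.approx(3 * t1["dissimilarity"], rel=1e-9)
        assert t2["template_signal"] == pytest.approx(t1["template_signal"], rel=1e-12)

    def test_mismatched_params_rejected(self, small_fshape):
        with pytest.raises(ValueError):
            evaluate_objective(small_fshape, [small_fshape], [], RegistrationConfig())


class TestRegisterSubject:
    def test_identity_is_stationary(self, small_fshape):
        cfg = RegistrationConfig()
        params, registered, trace = register_subject(small_fshape, small_fshape, cfg)
        assert abs(trace[-1] - trace[0]) < 1e-8
        assert np.abs(params.p).max() < 1e-6
        assert np.abs(params.zeta).max() < 1e-6

    def test_constant_signal_offset_absorbed_by_zeta(self, small_fshape):
        # with a negligible ζ penalty the optimum moves the whole offset into ζ
        cfg = RegistrationConfig(gamma_zeta=1e-8, tol=1e-7, max_iter=400)
        c = 5.0
        subject = FShape(small_fshape.mesh, small_fshape.signal + c)
        params, registered, trace = register_subject(small_fshape, subject, cfg)
        assert np.median(params.zeta) == pytest.approx(c, abs=0.5)

    def test_trace_non_increasing(self):
        cfg = RegistrationConfig(max_iter=15)
        a, b = tiny_fshape(11, n=3), tiny_fshape(12, n=3)
        _, _, trace = register_subject(a, b, cfg)
        assert all(x >= y - 1e-12 for x, y in zip(trace, trace[1:]))


class TestEstimateAtlas:
    def test_identical_subjects_give_identical_registrations(self, small_fshape):
        cfg = RegistrationConfig(max_iter=10)
        subjects = [
            FShape(small_fshape.mesh, small_fshape.signal.copy()) for _ in range(3)
        ]
        res = estimate_atlas(subjects, FShape(small_fshape.mesh, np.zeros_like(small_fshape.signal)), cfg)
        r0 = res.template.signal - res.registered[0].signal
        for reg in res.registered[1:]:
            np.testing.assert_allclose(res.template.signal - reg.signal, r0, atol=1e-9)

    def test_template_signal_moves_toward_subjects(self, small_fshape):
        cfg = RegistrationConfig(gamma_f=1e-10, gamma_w=10.0, max_iter=15)
        subjects = [FShape(small_fshape.mesh, small_fshape.signal.copy()) for _ in range(2)]
        hyper = FShape(small_fshape.mesh, np.zeros_like(small_fshape.signal))
        res = estimate_atlas(subjects, hyper, cfg)
        rms0 = np.sqrt(np.mean(small_fshape.signal**2))
        rms1 = np.sqrt(np.mean((res.template.signal - small_fshape.signal) ** 2))
        assert rms1 < 0.5 * rms0

    def test_trace_non_increasing_and_requires_two_subjects(self, small_fshape):
        cfg = RegistrationConfig(max_iter=6)
        with pytest.raises(ValueError):
            estimate_atlas([small_fshape], small_fshape, cfg)
        subs = [FShape(small_fshape.mesh, small_fshape.signal * s) for s in (0.9, 1.0, 1.1)]
        res = estimate_atlas(subs, FShape(small_fshape.mesh, np.zeros_like(small_fshape.signal)), cfg)
        tr = res.objective_trace
        assert all(x >= y - 1e-9 for x, y in zip(tr, tr[1:]))
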