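import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import biofilmsim as bs
from biofilmsim.fields import (
    assemble_c_system,
    assemble_phi_system,
    get_operators,
    growth_source,
    monod_rate,
    orientation,
    project_bounds,
    step_c,
    step_phi,
)
from conftest import make_state


# ---------------------------------------------------------------------------
# pointwise model functions
# ---------------------------------------------------------------------------

class TestMonodRate:
    @pytest.mark.parametrize(
        "c,r,k,expected",
        [(0.0, 100.0, 1.0, 0.0), (1.0, 100.0, 1.0, 50.0), (1e12, 100.0, 1.0, 100.0)],
    )
    def test_values(self, c, r, k, expected):
        assert monod_rate(c, r, k) == pytest.approx(expected, rel=1e-9)

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            monod_rate(-0.1, 100.0, 1.0)

    @given(st.floats(0.0, 10.0), st.floats(0.001, 10.0))
    @settings(derandomize=True, max_examples=50)
    def test_monotone_and_bounded(self, c, dc):
        lo = monod_rate(c, 100.0, 1.0)
        hi = monod_rate(c + dc, 100.0, 1.0)
        assert 0.0 <= lo <= hi < 100.0


class TestOrientation:
    @pytest.mark.parametrize(
        "gp,gc,expected",
        [
            ((1, 0, 0), (2, 0, 0), 1.0),
            ((1, 0, 0), (0, 3, 0), 0.0),
            ((-1, 0, 0), (5, 0, 0), -1.0),
        ],
    )
    def test_cosine(self, gp, gc, expected):
        assert orientation(gp, gc) == pytest.approx(expected)

    def test_degenerate_gradients_give_zero(self):
        assert orientation((0, 0, 0), (1, 0, 0)) == 0.0
        assert orientation((1, 0, 0), (1e-12, 0, 0), eps_grad=1e-8) == 0.0

    @given(st.lists(st.floats(-5, 5), min_size=6, max_size=6))
    @settings(derandomize=True, max_examples=50)
    def test_range(self, v):
        o = orientation(v[:3], v[3:])
        assert -1.0 - 1e-12 <= o <= 1.0 + 1e-12


class TestGrowthSource:
    def test_zero_without_nutrient_gradient(self):
        p = bs.MaterialParams()
        assert growth_source((1, 1, 1), 0.5, (0, 0, 0), p) == 0.0

    def test_zero_in_homogeneous_biofilm(self):
        p = bs.MaterialParams()
        assert growth_source((0, 0, 0), 0.5, (1, 0, 0), p) == 0.0

    def test_antiparallel_gradients_feed_growth(self):
        # h = monod(c) * (grad_phi . grad_c)/|grad_c| = -50 a for opposed
        # gradients at c=1, r=100, k=1; phi gains since h enters with +
        p = bs.MaterialParams()
        a, b = 0.7, 3.0
        got = growth_source((-a, 0, 0), 1.0, (b, 0, 0), p)
        assert got == pytest.approx(-50.0 * a, rel=1e-12)


class TestProjectBounds:
    def test_clamp_and_idempotence(self):
        x = np.array([-0.3, 0.5, 1.2])
        y = project_bounds(x, 0.0, 1.0)
        assert np.allclose(y, [0.0, 0.5, 1.0])
        assert np.allclose(project_bounds(y, 0.0, 1.0), y)

    def test_invalid_interval(self):
        with pytest.raises(ValueError):
            project_bounds(np.zeros(3), 1.0, 0.0)


# ---------------------------------------------------------------------------
# independent dense-assembly oracle
# ---------------------------------------------------------------------------

def _dense_scalar_matrices(mesh):
    """Mass and Laplacian matrices built entry-by-entry with an
    independent trilinear quadrature (product Gauss-Legendre rule)."""
    pts, wts = np.polynomial.legendre.leggauss(2)
    hx, hy, hz = mesh.spacing
    signs = [(-1, -1, -1), (1, -1, -1), (1, 1, -1), (-1, 1, -1),
             (-1, -1, 1), (1, -1, 1), (1, 1, 1), (-1, 1, 1)]

    def shape(a, xi, et, ze):
        sx, sy, sz = signs[a]
        return (1 + sx * xi) * (1 + sy * et) * (1 + sz * ze) / 8.0

    def grad(a, xi, et, ze):
        sx, sy, sz = signs[a]
        return np.array([
            sx * (1 + sy * et) * (1 + sz * ze) / 8.0 * 2 / hx,
            (1 + sx * xi) * sy * (1 + sz * ze) / 8.0 * 2 / hy,
            (1 + sx * xi) * (1 + sy * et) * sz / 8.0 * 2 / hz,
        ])

    n = mesh.n_nodes
    M = np.zeros((n, n))
    K = np.zeros((n, n))
    detJ = hx * hy * hz / 8.0
    for e in np.nonzero(mesh.active_mask)[0]:
        conn = mesh.element_conn[e]
        for ix, xi in enumerate(pts):
            for iy, et in enumerate(pts):
                for iz, ze in enumerate(pts):
                    w = wts[ix] * wts[iy] * wts[iz] * detJ
                    for a in range(8):
                        Na = shape(a, xi, et, ze)
                        ga = grad(a, xi, et, ze)
                        for b in range(8):
                            M[conn[a], conn[b]] += w * Na * shape(b, xi, et, ze)
                            K[conn[a], conn[b]] += w * ga @ grad(b, xi, et, ze)
    return M, K


def _dense_advection(mesh, c, params):
    pts, wts = np.polynomial.legendre.leggauss(2)
    hx, hy, hz = mesh.spacing
    signs = [(-1, -1, -1), (1, -1, -1), (1, 1, -1), (-1, 1, -1),
             (-1, -1, 1), (1, -1, 1), (1, 1, 1), (-1, 1, 1)]

    def shape(a, xi, et, ze):
        sx, sy, sz = signs[a]
        return (1 + sx * xi) * (1 + sy * et) * (1 + sz * ze) / 8.0

    def grad(a, xi, et, ze):
        sx, sy, sz = signs[a]
        return np.array([
            sx * (1 + sy * et) * (1 + sz * ze) / 8.0 * 2 / hx,
            (1 + sx * xi) * sy * (1 + sz * ze) / 8.0 * 2 / hy,
            (1 + sx * xi) * (1 + sy * et) * sz / 8.0 * 2 / hz,
        ])

    n = mesh.n_nodes
    A = np.zeros((n, n))
    detJ = hx * hy * hz / 8.0
    for e in np.nonzero(mesh.active_mask)[0]:
        conn = mesh.element_conn[e]
        for ix, xi in enumerate(pts):
            for iy, et in enumerate(pts):
                for iz, ze in enumerate(pts):
                    w = wts[ix] * wts[iy] * wts[iz] * detJ
                    c_gp = sum(shape(a, xi, et, ze) * c[conn[a]] for a in range(8))
                    g_gp = sum(grad(a, xi, et, ze) * c[conn[a]] for a in range(8))
                    norm = np.linalg.norm(g_gp)
                    if norm < params.eps_grad:
                        continue
                    coeff = monod_rate(max(c_gp, 0.0), params.r, params.k)
                    direction = g_gp / norm
                    for a in range(8):
                        Na = shape(a, xi, et, ze)
                        for b in range(8):
                            A[conn[a], conn[b]] += (
                                w * Na * coeff * (direction @ grad(b, xi, et, ze))
                            )
    return A


class TestAssemblyAgainstDenseOracle:
    """Sparse assembled systems must equal the brute-force dense ones."""

    def setup_method(self):
        # modest-magnitude constants so entrywise comparison at 1e-12 is
        # meaningful; assembly is parameter-agnostic
        self.params = bs.MaterialParams(
            d=1.3, beta=0.7, g=2.0, r=5.0, k=0.5, k_alpha=0.1, c_shutoff=0.0
        )

    def _mesh_and_state(self):
        mesh = bs.build_box_mesh((3.0, 2.0, 1.0), 1.0)  # 24 nodes <= 50
        rng = np.random.default_rng(7)
        state = make_state(mesh)
        state.c = rng.uniform(0.1, 0.9, mesh.n_nodes)
        state.phi = rng.uniform(0.0, 1.0, mesh.n_nodes)
        state.alpha = rng.uniform(0.0, 0.2, (mesh.n_elements, 8))
        return mesh, state

    def test_c_system_matches(self):
        mesh, state = self._mesh_and_state()
        dt = 0.05
        S, rhs = assemble_c_system(state, mesh, None, dt, self.params)
        Md, Kd = _dense_scalar_matrices(mesh)
        S_dense = Md / dt + self.params.d * Kd
        assert np.abs(S.toarray() - S_dense).max() <= 1e-12
        rhs_dense = Md @ (state.c / dt) - self.params.g * (Md @ state.phi)
        assert np.abs(rhs - rhs_dense).max() <= 1e-12

    def test_phi_system_matches(self):
        mesh, state = self._mesh_and_state()
        dt = 0.05
        S, rhs = assemble_phi_system(state, mesh, None, dt, self.params, state.c)
        Md, Kd = _dense_scalar_matrices(mesh)
        Ad = _dense_advection(mesh, state.c, self.params)
        S_dense = Md / dt + self.params.beta * Kd + Ad
        assert np.abs(S.toarray() - S_dense).max() <= 1e-12

    def test_c_shutoff_diagonal_matches(self):
        mesh, state = self._mesh_and_state()
        params = bs.MaterialParams(d=1.3, g=2.0, c_shutoff=0.05)
        dt = 0.05
        S, _ = assemble_c_system(state, mesh, None, dt, params, c_lin=state.c)
        Md, Kd = _dense_scalar_matrices(mesh)
        w = Md.sum(axis=1)
        diag = np.diag(params.g * state.phi / (state.c + params.c_shutoff) * w)
        S_dense = Md / dt + params.d * Kd + diag
        assert np.abs(S.toarray() - S_dense).max() <= 1e-12


# ---------------------------------------------------------------------------
# nutrient steps
# ---------------------------------------------------------------------------

class TestStepC:
    def test_uniform_field_is_steady_without_sources(self, small_box):
        state = make_state(small_box, phi=0.0, c=0.37)
        c1 = step_c(state, small_box, None, 0.01, bs.MaterialParams(g=0.0, d=1.0))
        assert np.allclose(c1, 0.37, atol=1e-12)

    def test_mass_conservation_under_zero_flux(self, small_box):
        ops = get_operators(small_box)
        rng = np.random.default_rng(3)
        state = make_state(small_box)
        state.c = 0.2 + 0.6 * rng.random(small_box.n_nodes)
        params = bs.MaterialParams(g=0.0, d=1.0)
        total0 = ops.node_weights @ state.c
        for _ in range(25):
            state.c = step_c(state, small_box, None, 0.02, params)
        total1 = ops.node_weights @ state.c
        assert abs(total1 - total0) / total0 <= 1e-10

    def test_rod_relaxes_to_dirichlet_value(self, rod):
        rod.node_sets["src"] = rod.node_sets["xmin"]
        bvp = bs.BVPSpec("agar", (8, 1, 1), rod.spacing, ("src", 1.0),
                         phi_init_set="xmin", mech_constraints=[])
        state = make_state(rod, phi=0.0, c=0.0)
        params = bs.MaterialParams(g=0.0, d=1.0)
        for _ in range(120):
            state.c = step_c(state, rod, bvp, 50.0, params)
        # dense-matrix steady state of the 1D chain with one end held at 1
        assert np.abs(state.c - 1.0).max() <= 1e-9

    def test_result_stays_in_bounds_with_strong_sink(self, small_box):
        state = make_state(small_box, phi=1.0, c=0.5)
        c1 = step_c(state, small_box, None, 0.1, bs.MaterialParams(g=100.0, d=1.0))
        assert c1.min() >= 0.0 and c1.max() <= 1.0


class TestStepPhi:
    def test_uniform_state_is_steady(self, small_box):
        state = make_state(small_box, phi=0.4, c=0.8)
        phi1 = step_phi(state, small_box, None, 0.01, bs.MaterialParams())
        assert np.allclose(phi1, 0.4, atol=1e-10)

    def test_local_expansion_source_raises_phi(self, small_box):
        # with flat fields only the k_alpha*alpha source survives
        state = make_state(small_box, phi=0.2, c=0.5)
        state.alpha[:] = 0.5
        params = bs.MaterialParams(k_alpha=0.01)
        dt = 0.1
        phi1 = step_phi(state, small_box, None, dt, params)
        assert np.allclose(phi1, 0.2 + dt * params.k_alpha * 0.5, atol=1e-10)

    def test_front_advances_toward_nutrient_source(self, rod):
        # biofilm block at the left, nutrients held at the right end
        rod.node_sets["src"] = rod.node_sets["xmax"]
        bvp = bs.BVPSpec("agar", (8, 1, 1), rod.spacing, ("src", 1.0),
                         phi_init_set="xmin", mech_constraints=[])
        state = make_state(rod)
        x = rod.node_coords[:, 0]
        state.phi = np.where(x <= 2.0 + 1e-9, 1.0, 0.0)
        params = bs.MaterialParams(d=1.0, g=0.0, beta=0.01, r=5.0)
        state.c = step_c(state, rod, bvp, 0.5, params)
        interface = np.nonzero(np.abs(x - 3.0) < 1e-9)[0]
        before = state.phi[interface].mean()
        phi1 = step_phi(state, rod, bvp, 0.2, params, c_new=state.c)
        assert phi1[interface].mean() > before

    def test_diffusion_mode_decay_matches_closed_form(self, rod):
        """With no nutrient gradient the phi step is pure implicit
        diffusion; a discrete (K, M) eigenmode must decay by exactly
        1/(1 + lambda beta dt)."""
        import scipy.linalg as la

        ops = get_operators(rod)
        M = ops.M.toarray()
        K = ops.K.toarray()
        lam, vecs = la.eigh(K, M)
        idx = np.argsort(lam)[1]  # first non-constant mode
        lam1, v1 = lam[idx], vecs[:, idx]
        v1 = v1 / np.abs(v1).max()
        params = bs.MaterialParams(beta=0.5, g=0.0, r=0.0, k_alpha=0.0)
        dt = 0.05
        state = make_state(rod, c=0.3)
        state.phi = 0.5 + 0.1 * v1
        phi1 = step_phi(state, rod, None, dt, params)
        expected = 0.5 + 0.1 * v1 / (1.0 + lam1 * params.beta * dt)
        assert np.abs(phi1 - expected).max() <= 1e-9

    def test_bounds_enforced(self, small_box):
        rng = np.random.default_rng(11)
        state = make_state(small_box)
        state.phi = rng.uniform(0, 1, small_box.n_nodes)
        state.c = rng.uniform(0, 1, small_box.n_nodes)
        state.alpha[:] = 5.0
        phi1 = step_phi(state, small_box, None, 1.0, bs.MaterialParams(k_alpha=1.0))
        assert phi1.min() >= 0.0 and phi1.max() <= 1.0
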