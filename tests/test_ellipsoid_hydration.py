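import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.spatial.transform import Rotation

from conftest import ca_trajectory

from ionshell.core_io import Frame, Trajectory, select
from ionshell.ellipsoid_hydration import (
    INNER_CORE,
    OUTSIDE,
    assign_layer,
    assign_layers,
    build_layers,
    density_profile,
    fit_ellipsoid,
    layer_volume,
)
from ionshell.synthetic_data import EllipsoidSystemSpec, gen_ellipsoid_system


def corner_cloud():
    """8 points at (+-1, +-2, +-3): covariance diag(1, 4, 9)."""
    pts = np.array(
        [[sx, 2 * sy, 3 * sz] for sx in (-1, 1) for sy in (-1, 1) for sz in (-1, 1)],
        float,
    )
    traj = ca_trajectory(pts[None])
    return traj.topology, Frame(coordinates=pts)


@pytest.fixture
def corner_fit():
    top, frame = corner_cloud()
    return fit_ellipsoid(frame, select(top, "name CA"))


class TestFitEllipsoid:
    def test_corner_cloud_eigenvalues_and_semiaxes(self, corner_fit):
        np.testing.assert_allclose(corner_fit.eigenvalues, [9.0, 4.0, 1.0], atol=1e-12)
        np.testing.assert_allclose(corner_fit.semiaxes, [6.0, 4.0, 2.0], atol=1e-12)
        np.testing.assert_allclose(corner_fit.center, 0.0, atol=1e-14)
        # axes are the coordinate axes (major = z, minor = x)
        np.testing.assert_allclose(np.abs(corner_fit.axes), np.eye(3)[::-1], atol=1e-12)

    def test_rotational_equivariance(self, corner_fit):
        top, frame = corner_cloud()
        R = Rotation.from_euler("zyx", [30, 45, 60], degrees=True).as_matrix()
        rotated = Frame(coordinates=frame.coordinates @ R.T + np.array([1.0, 2.0, 3.0]))
        fit2 = fit_ellipsoid(rotated, select(top, "name CA"))
        np.testing.assert_allclose(fit2.eigenvalues, corner_fit.eigenvalues, atol=1e-12)
        np.testing.assert_allclose(fit2.center, [1.0, 2.0, 3.0], atol=1e-12)
        for row, ref in zip(fit2.axes, corner_fit.axes):
            assert abs(abs(row @ R @ ref) - 1.0) < 1e-10

    def test_uniform_solid_recovers_two_over_sqrt5_of_semiaxis(self):
        spec = EllipsoidSystemSpec(
            semiaxes=(3.0, 2.0, 1.0),
            n_protein_points=100_000,
            water_density=0.0,
            box=(12.0, 12.0, 12.0),
            seed=13,
        )
        traj = gen_ellipsoid_system(spec)
        fit = fit_ellipsoid(traj.frames[0], select(traj.topology, "role protein"))
        expected = 2.0 / np.sqrt(5.0) * np.array([3.0, 2.0, 1.0])
        np.testing.assert_allclose(fit.semiaxes, expected, rtol=0.02)

    def test_coplanar_points_rejected(self):
        pts = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0]], float)
        traj = ca_trajectory(pts[None])
        with pytest.raises(ValueError, match="coplanar"):
            fit_ellipsoid(traj.frames[0], select(traj.topology, "name CA"))


class TestLayers:
    def test_increment_formula(self, corner_fit):
        scheme = build_layers(corner_fit, 0.03, (0, 10))
        np.testing.assert_allclose(
            scheme.deltas, [0.03, 0.03 * 4 / 9, 0.03 * 1 / 9], atol=1e-15
        )

    def test_sqrt_scaling_option(self, corner_fit):
        scheme = build_layers(corner_fit, 0.03, (0, 10), increment_scaling="sqrt_eigenvalue")
        np.testing.assert_allclose(scheme.deltas, [0.03, 0.02, 0.01], atol=1e-15)

    def test_zero_delta_rejected(self, corner_fit):
        with pytest.raises(ValueError, match="delta0"):
            build_layers(corner_fit, 0.0, (0, 10))

    def test_too_negative_nmin_names_axis(self, corner_fit):
        with pytest.raises(ValueError, match="axis 0"):
            build_layers(corner_fit, 0.03, (-201, 10))

    def test_layer_volume_closed_form(self, corner_fit):
        scheme = build_layers(corner_fit, 0.03, (0, 10))
        a = np.array([6.0, 4.0, 2.0])
        d = np.array([0.03, 0.04 / 3, 0.01 / 3])
        v_manual = 4 / 3 * np.pi * (np.prod(a + d) - np.prod(a))
        assert layer_volume(scheme, 0) == pytest.approx(v_manual, rel=1e-12)
        assert v_manual == pytest.approx(2.02, abs=0.01)

    def test_layer_volume_monte_carlo_oracle(self, corner_fit):
        scheme = build_layers(corner_fit, 0.2, (0, 3))
        rng = np.random.default_rng(99)
        outer = scheme.semiaxes_at(4)
        n_mc = 2_000_000
        # sample a bounding box in the ellipsoid's body frame, map to lab frame
        pts = ((rng.random((n_mc, 3)) * 2 - 1) * outer) @ scheme.base.axes
        box_vol = float(np.prod(2 * outer))
        lab = assign_layers(pts, scheme)
        for n in range(0, 4):
            frac = np.mean(lab == n)
            mc_vol = frac * box_vol
            se = box_vol * np.sqrt(frac * (1 - frac) / n_mc)
            assert abs(mc_vol - layer_volume(scheme, n)) < 4 * se

    def test_volumes_telescope(self, corner_fit):
        scheme = build_layers(corner_fit, 0.03, (0, 10))
        total = sum(layer_volume(scheme, n) for n in range(0, 10))
        expected = scheme.ellipsoid_volume_at(10) - scheme.ellipsoid_volume_at(0)
        assert total == pytest.approx(expected, rel=1e-10)

    @given(
        lam=st.tuples(
            st.floats(1.0, 9.0), st.floats(0.3, 0.9), st.floats(0.05, 0.25)
        ),
        delta0=st.floats(0.01, 0.2),
    )
    def test_volume_positive_and_telescoping_property(self, lam, delta0):
        pts = np.array(
            [
                [sx * np.sqrt(lam[2]), sy * np.sqrt(lam[1]), sz * np.sqrt(lam[0])]
                for sx in (-1, 1)
                for sy in (-1, 1)
                for sz in (-1, 1)
            ]
        )
        traj = ca_trajectory(pts[None])
        fit = fit_ellipsoid(traj.frames[0], select(traj.topology, "name CA"))
        scheme = build_layers(fit, delta0, (0, 5))
        vols = [layer_volume(scheme, n) for n in range(0, 6)]
        assert all(v > 0 for v in vols)
        assert sum(vols) == pytest.approx(
            scheme.ellipsoid_volume_at(6) - scheme.ellipsoid_volume_at(0), rel=1e-9
        )


class TestAssignLayer:
    def test_center_is_inner_core(self, corner_fit):
        scheme = build_layers(corner_fit, 0.03, (-5, 10))
        assert assign_layer(np.zeros(3), scheme) == INNER_CORE

    def test_point_on_base_surface_is_layer_zero(self, corner_fit):
        scheme = build_layers(corner_fit, 0.03, (-5, 10))
        # major semiaxis is along z for this cloud
        assert assign_layer(np.array([0.0, 0.0, 6.0]), scheme) == 0

    def test_far_point_is_outside(self, corner_fit):
        scheme = build_layers(corner_fit, 0.03, (-5, 10))
        assert assign_layer(np.array([50.0, 0.0, 0.0]), scheme) == OUTSIDE

    def test_matches_brute_force_scan(self, corner_fit):
        """Exhaustive oracle: evaluate E_n for every n at every point."""
        scheme = build_layers(corner_fit, 0.05, (-10, 30))
        rng = np.random.default_rng(4)
        pts = rng.uniform(-9, 9, size=(10_000, 3))
        fast = assign_layers(pts, scheme)
        q = scheme.base.to_body_frame(pts)
        for i in range(pts.shape[0]):
            label = None
            for n in range(scheme.n_min, scheme.n_max + 1):
                e_n = np.sum((q[i] / scheme.semiaxes_at(n)) ** 2)
                e_next = np.sum((q[i] / scheme.semiaxes_at(n + 1)) ** 2)
                if e_n >= 1.0 and e_next < 1.0:
                    label = n
                    break
            if label is None:
                e_min = np.sum((q[i] / scheme.semiaxes_at(scheme.n_min)) ** 2)
                label = scheme.n_min - 1 if e_min < 1.0 else scheme.n_max + 1
            assert fast[i] == label


@pytest.fixture(scope="module")
def uniform_system():
    spec = EllipsoidSystemSpec(
        semiaxes=(3.0, 2.0, 1.0),
        n_protein_points=4000,
        water_density=10.0,
        ion_densities={"NA": 0.3},
        box=(12.0, 12.0, 12.0),
        n_frames=3,
        seed=23,
    )
    return gen_ellipsoid_system(spec)


class TestDensityProfile:
    def profile(self, traj, **kw):
        top = traj.topology
        return density_profile(
            traj,
            protein_sel=select(top, "role protein"),
            water_sel=select(top, "role water"),
            ion_sels={"NA": select(top, "resname NA and role ion")},
            **kw,
        )

    def test_total_count_conservation(self, uniform_system):
        prof = self.profile(uniform_system, n_range=(-5, 60))
        n_water = uniform_system.topology.water_oxygen_indices().size
        assert prof.table["water_count_mean"].sum() == pytest.approx(n_water, abs=1e-9)
        n_na = int(np.sum(uniform_system.topology.resnames == "NA"))
        assert prof.table["NA_count_mean"].sum() == pytest.approx(n_na, abs=1e-9)

    def test_water_free_system_all_zero(self):
        spec = EllipsoidSystemSpec(
            semiaxes=(2.0, 1.5, 1.0),
            n_protein_points=500,
            water_density=0.0,
            box=(8.0, 8.0, 8.0),
            seed=2,
        )
        traj = gen_ellipsoid_system(spec)
        prof = density_profile(
            traj,
            protein_sel=select(traj.topology, "role protein"),
            water_sel=select(traj.topology, "role water"),
            n_range=(0, 30),
        )
        assert prof.table["water_rho_mean"].abs().max() == 0.0

    def test_rigid_motion_invariance(self):
        spec = EllipsoidSystemSpec(
            semiaxes=(2.0, 1.5, 1.0),
            n_protein_points=1000,
            water_density=3.0,
            box=(8.0, 8.0, 8.0),
            seed=31,
        )
        traj = gen_ellipsoid_system(spec)
        # drop the box so rotation is legitimate (no PBC wrap)
        plain = Trajectory(traj.topology, [Frame(coordinates=traj.frames[0].coordinates)])
        R = Rotation.from_euler("xyz", [15, 25, 35], degrees=True).as_matrix()
        moved = Trajectory(
            traj.topology,
            [Frame(coordinates=traj.frames[0].coordinates @ R.T + np.array([3.0, -1.0, 2.0]))],
        )
        kw = dict(
            protein_sel=select(traj.topology, "role protein"),
            water_sel=select(traj.topology, "role water"),
            n_range=(0, 40),
        )
        a = density_profile(plain, **kw).table
        b = density_profile(moved, **kw).table
        rho_a = a.loc[a.region == "layer", "water_rho_mean"].to_numpy()
        rho_b = b.loc[b.region == "layer", "water_rho_mean"].to_numpy()
        np.testing.assert_allclose(rho_a, rho_b, rtol=1e-10, atol=1e-12)

    def test_coarse_layers_conserve_fine_counts(self, uniform_system):
        one_frame = Trajectory(uniform_system.topology, uniform_system.frames[:1])
        fine = self.profile(one_frame, delta0=0.03, n_range=(0, 19)).table
        coarse = self.profile(one_frame, delta0=0.06, n_range=(0, 9)).table
        fine_counts = fine.loc[fine.region == "layer", "water_count_mean"].to_numpy()
        coarse_counts = coarse.loc[coarse.region == "layer", "water_count_mean"].to_numpy()
        np.testing.assert_allclose(
            coarse_counts, fine_counts[::2] + fine_counts[1::2], atol=1e-9
        )

    def test_two_density_crossover_located_within_one_layer(self):
        """Dense inner shell vs sparse far field around a spherical particle."""
        rng = np.random.default_rng(77)
        s, R_bound, box = 1.5, 2.5, np.array([10.0, 10.0, 10.0])
        center = box / 2
        n_prot = 5000
        v = rng.standard_normal((n_prot, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        prot = center + s * v * rng.random(n_prot)[:, None] ** (1 / 3)

        def sample_shell(n, rho_ok):
            out = np.empty((0, 3))
            while out.shape[0] < n:
                pts = rng.random((4 * n, 3)) * box
                r = np.linalg.norm(pts - center, axis=1)
                out = np.vstack([out, pts[rho_ok(r)]])
            return out[:n]

        rho_in, rho_out = 30.0, 5.0
        v_in = 4 / 3 * np.pi * (R_bound**3 - s**3)
        v_out = float(np.prod(box)) - 4 / 3 * np.pi * R_bound**3
        dense = sample_shell(int(rho_in * v_in), lambda r: (r >= s) & (r < R_bound))
        sparse = sample_shell(int(rho_out * v_out), lambda r: r >= R_bound)
        waters = np.vstack([dense, sparse])

        from ionshell.core_io import Atom, Topology

        atoms = [Atom(i, "CA", "C", "ALA", i + 1, "A", "protein") for i in range(n_prot)]
        for k in range(waters.shape[0]):
            atoms.append(
                Atom(len(atoms), "OW", "O", "SOL", n_prot + k + 1, "", "water")
            )
        top = Topology(atoms)
        traj = Trajectory(top, [Frame(coordinates=np.vstack([prot, waters]), box=box)])
        prof = density_profile(
            traj,
            protein_sel=select(top, "role protein"),
            water_sel=select(top, "role water"),
            delta0=0.05,
            n_range=(0, 60),
        )
        tab = prof.table[prof.table.region == "layer"]
        mid = 0.5 * (rho_in + rho_out)
        solvated = tab[tab.r_nm > s + 0.05]
        below = solvated[solvated.water_rho_mean < mid]
        crossover_r = float(below.r_nm.iloc[0])
        assert abs(crossover_r - R_bound) <= 2 * 0.05  # within one layer width each side

    def test_overlapping_selections_rejected(self, uniform_system):
        top = uniform_system.topology
        with pytest.raises(ValueError, match="disjoint"):
            density_profile(
                uniform_system,
                protein_sel=select(top, "role protein or role water"),
                water_sel=select(top, "role water"),
            )
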