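"""Flow-solver oracles: Darcy column, Poiseuille tube, membrane sandwich,
conservation, linearity and boundary handling."""

import numpy as np
import pytest

from pulmolymph.core import FluidParameters, LABEL_INTERSTITIUM, LabelVolume
from pulmolymph.microflow import (
    SingularSystemError,
    assemble,
    domain_fluxes,
    export_fields,
    read_vtk_fields,
    solve,
)
from pulmolymph.model_prep import (
    BoundarySpec,
    boundary_patch,
    model_from_labels,
    prepare_model_volume,
)
from pulmolymph.synthetic import generate_validation_geometry

from conftest import make_tube_model, pressure_driven_tube_boundaries

PARAMS = FluidParameters()
EMPTY_BOUNDS = BoundarySpec(distal_faces=("+z", "-y", "+y"),
                            inlets={"blood": [], "lymph": []},
                            outlets={"blood": [], "lymph": []})


def _darcy_slab(n=20, pitch=5.0):
    vol = generate_validation_geometry("slab", shape=(n, n, n),
                                       voxel_pitch=pitch)
    return prepare_model_volume(vol, voi=None, upsample=1, median_window=1)


class TestDarcyOracle:
    def test_1d_column_matches_closed_form_to_machine_precision(self):
        model = _darcy_slab()
        system = assemble(model, EMPTY_BOUNDS, PARAMS,
                          interstitial_bc={"-z": 100.0, "+z": 0.0})
        sol = solve(system, tol=1e-12)
        v = sol.face_velocity[0][0]
        analytic = PARAMS.k * 100.0 / (PARAMS.mu * 100e-6)
        assert np.allclose(v, analytic, rtol=1e-8)
        assert sol.fluxes.balance_defect["interstitium"] <= 1e-8

    def test_pure_darcy_matrix_is_seven_point_laplacian(self):
        model = _darcy_slab(n=8)
        system = assemble(model, EMPTY_BOUNDS, PARAMS,
                          interstitial_bc={"-z": 1.0, "+z": 0.0})
        C = system.C.tocsr()
        g = PARAMS.k * (5e-6)**2 / (PARAMS.mu * 5e-6)
        # an interior cell: 6 off-diagonal entries of -g, diagonal 6g
        i = int(system.pidx[4, 4, 4])
        row = C.getrow(i)
        off = row.toarray().ravel()
        assert off[i] == pytest.approx(6 * g)
        assert sorted(off[off != off[i]])[:6] == pytest.approx([-g] * 6)
        assert system.n_u == 0   # no lumen cells -> no Stokes unknowns

    def test_sealed_box_with_uniform_pressure_has_zero_flux(self):
        model = _darcy_slab(n=12)
        system = assemble(model, EMPTY_BOUNDS, PARAMS, interstitial_bc=-1064.0)
        sol = solve(system, tol=1e-12)
        rep = domain_fluxes(sol, system)
        assert abs(rep.interstitial_exchange_in) < 1e-25
        assert np.allclose(sol.u_cell[np.isfinite(sol.u_cell)], 0.0,
                           atol=1e-18)


class TestStokesOracle:
    def test_poiseuille_flow_and_refinement(self):
        errs = []
        for radius, length, pitch in ((8, 24, 10.0), (16, 24, 5.0)):
            model = make_tube_model(radius, length, pitch)
            bounds, pres = pressure_driven_tube_boundaries(model, 100.0, 0.0)
            system = assemble(model, bounds, PARAMS, interstitial_bc=None,
                              outlet_pressures=pres)
            sol = solve(system, tol=1e-10, suppress_backflow=False)
            h = pitch * 1e-6
            Q = sol.face_velocity[0][-1].sum() * h * h
            # Dirichlet pressures act at ghost centres one cell beyond the
            # tube, so the pressure drop spans (n + 1) cells
            L = (length + 1) * h
            Q_an = np.pi * (radius * h)**4 * 100.0 / (8 * PARAMS.mu * L)
            errs.append(abs(Q - Q_an) / Q_an)
            assert sol.fluxes.balance_defect["blood"] <= 1e-8
        assert errs[0] <= 0.10
        assert errs[1] < errs[0]   # halving the pitch reduces the error

    def test_grid_without_lumen_allocates_no_stokes_unknowns(self):
        model = _darcy_slab(n=8)
        system = assemble(model, EMPTY_BOUNDS, PARAMS,
                          interstitial_bc={"-z": 1.0, "+z": 0.0})
        assert system.n_u == 0


class TestMembraneOracle:
    def _sandwich(self, pitch=5.0, t_vox=10):
        vol = generate_validation_geometry("sandwich", thickness=t_vox,
                                           lumen_thickness=8, side=24,
                                           voxel_pitch=pitch)
        model = model_from_labels(vol)
        bounds = BoundarySpec(
            distal_faces=("+z", "-y", "+y"),
            inlets={"blood": [], "lymph": []},
            outlets={"blood": [boundary_patch(model, "blood", "-z")],
                     "lymph": [boundary_patch(model, "lymph", "+z")]})
        return model, bounds

    def test_series_resistance_flux_within_two_percent(self):
        model, bounds = self._sandwich()
        system = assemble(model, bounds, PARAMS, interstitial_bc=None)
        sol = solve(system, tol=1e-12, suppress_backflow=False)
        h = 5e-6
        area = 24 * 24 * h * h
        R = 1 / PARAMS.K_B + PARAMS.mu * 10 * h / PARAMS.k + 1 / PARAMS.K_L
        analytic = (PARAMS.p_B - PARAMS.p_L) / R
        assert abs(sol.fluxes.Q_L_in / area - analytic) / analytic <= 0.02
        assert sol.fluxes.Q_B_out == pytest.approx(sol.fluxes.Q_L_in,
                                                   rel=1e-6)

    def test_membrane_face_flux_equals_conductivity_times_dp(self):
        # two-cell check of the membrane relation with table parameters:
        # fixed pressures 2000 / -1064 Pa give K_B * 3064 = 8.30e-9 m/s
        model, bounds = self._sandwich()
        system = assemble(model, bounds, PARAMS, interstitial_bc=None)
        v = PARAMS.K_B * (2000.0 - (-1064.0))
        assert v == pytest.approx(8.30e-9, rel=0.01)
        # the assembled C block carries exactly K*A on membrane pairs
        h = model.voxel_pitch * 1e-6
        i = int(system.pidx[7, 12, 12])    # last blood slab cell
        j = int(system.pidx[8, 12, 12])    # first interstitial cell
        assert system.C[i, j] == pytest.approx(-PARAMS.K_B * h * h)

    def test_conservation_on_all_analytic_geometries(self):
        model, bounds = self._sandwich()
        system = assemble(model, bounds, PARAMS, interstitial_bc=None)
        sol = solve(system, tol=1e-12, suppress_backflow=False)
        for dom, defect in sol.fluxes.balance_defect.items():
            assert defect <= 1e-8, dom


class TestProperties:
    def test_linearity_in_driving_pressures(self):
        model = make_tube_model(6, 20, 10.0)
        bounds, pres = pressure_driven_tube_boundaries(model, 50.0, 0.0)
        q = []
        for alpha in (1.0, 2.0):
            scaled = {k: v * alpha for k, v in pres.items()}
            system = assemble(model, bounds, PARAMS, interstitial_bc=None,
                              outlet_pressures=scaled)
            sol = solve(system, tol=1e-12, suppress_backflow=False)
            h = 10e-6
            q.append(sol.face_velocity[0][-1].sum() * h * h)
        assert q[1] == pytest.approx(2 * q[0], rel=1e-6)

    def test_backflow_suppression_closes_inflowing_outlet(self):
        # T-shaped tube: inlet at -z, a normal outlet at +z, and a side
        # outlet on +y held at a pressure that would draw fluid in; the
        # suppression loop must convert the side outlet to a wall while
        # the +z outlet keeps the system anchored
        from pulmolymph.core import LABEL_BLOOD, LabelVolume
        n = 25
        labels = np.zeros((n, n, n), dtype=np.uint8)
        c = n // 2
        yy, xx = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
        labels[:, np.hypot(yy - c, xx - c) <= 4] = LABEL_BLOOD
        zz2, xx2 = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
        branch = np.hypot(zz2 - c, xx2 - c) <= 4
        for y in range(c, n):
            labels[:, y, :][branch] = LABEL_BLOOD
        model = model_from_labels(LabelVolume(labels, 10.0))
        bounds = BoundarySpec(
            distal_faces=("-z", "-y", "+x"),
            inlets={"blood": [boundary_patch(model, "blood", "-z")],
                    "lymph": []},
            outlets={"blood": [boundary_patch(model, "blood", "+z"),
                               boundary_patch(model, "blood", "+y")],
                     "lymph": []})
        system = assemble(model, bounds, PARAMS, interstitial_bc=None,
                          inlet_velocities={("blood", 0): 1e-4},
                          outlet_pressures={("blood", 0): 0.0,
                                            ("blood", 1): 1e4})
        sol = solve(system, tol=1e-10, max_backflow_iters=20)
        assert sol.suppressed_outlet_faces > 0
        assert not sol.backflow_flagged
        # after suppression no remaining outlet face carries inflow
        for d in range(3):
            ft = system.ftype[d]
            for row in np.argwhere(ft == 2):
                outward = -1.0 if row[d] == 0 else 1.0
                v = sol.face_velocity[d][tuple(row)]
                assert outward * v >= -1e-16

    def test_unforced_system_raises_before_solve(self):
        model = _darcy_slab(n=8)
        with pytest.raises(SingularSystemError):
            assemble(model, EMPTY_BOUNDS, PARAMS, interstitial_bc=None)


class TestExport:
    def test_round_trip_and_field_names(self, tmp_path, intralobular_voi):
        vol, _ = intralobular_voi
        model = prepare_model_volume(vol, voi=None, upsample=1,
                                     median_window=1)
        from pulmolymph.model_prep import identify_vessel_openings
        bounds = identify_vessel_openings(model, "-z")
        system = assemble(model, bounds, PARAMS)
        sol = solve(system, tol=1e-8)
        path = tmp_path / "fields.vtk"
        export_fields(sol, model, path)
        fields = read_vtk_fields(path)
        assert set(fields) == {"pressure", "domain", "velocity"}
        expected = np.where(np.isfinite(sol.p), sol.p, 0.0)
        assert np.allclose(fields["pressure"], expected, rtol=1e-9,
                           atol=1e-12)

    def test_empty_solution_export_refused(self, tmp_path):
        from pulmolymph.microflow import FlowSolution
        empty = FlowSolution(p=np.full((2, 2, 2), np.nan),
                             u_cell=np.zeros((3, 2, 2, 2)),
                             face_velocity=[], residuals={},
                             suppressed_outlet_faces=0,
                             backflow_flagged=False)
        with pytest.raises(ValueError):
            export_fields(empty, None, tmp_path / "x.vtk")
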