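import numpy as np
import pytest

from mebci.forward.analytic import (
    Dipole,
    ShellModel,
    analytic_three_sphere_potential,
)
from mebci.forward.bem import (
    LeadField,
    bem_leadfield,
    leadfield_from_solution,
    place_dipole,
    project_to_scalp,
)
from mebci.forward.montage import standard_montage


@pytest.fixture(scope="module")
def montage():
    return standard_montage(scalp_radius=0.1)


class TestBemOracle:
    def test_against_analytic_series_coarse(self, coarse_bem_solution, montage):
        """Constant-collocation BEM on a 320-triangle mesh vs the series."""
        shell = ShellModel()
        rng = np.random.default_rng(7)
        errs = []
        for _ in range(6):
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            pos = u * rng.uniform(0.0, 0.6) * 0.087
            mom = rng.normal(size=3)
            mom = mom / np.linalg.norm(mom) * 1e-8
            lf = leadfield_from_solution(
                coarse_bem_solution, [Dipole(pos, mom)], reference=None
            )
            vb = lf.matrix @ mom
            va = np.array(
                [
                    analytic_three_sphere_potential(Dipole(pos, mom), e, shell, 100)
                    for e in montage.positions
                ]
            )
            va -= va.mean()
            vb -= vb.mean()
            errs.append(np.linalg.norm(vb - va) / np.linalg.norm(va))
        assert np.median(errs) < 0.10  # coarse mesh; acceptance uses 1280 tris

    def test_moment_linearity(self, coarse_bem_solution):
        d = Dipole([0, 0, 0.04], [1e-8, 0, 0])
        lf = leadfield_from_solution(coarse_bem_solution, [d], reference=None)
        g1 = lf.gains(0, [1e-8, 0, 0])
        g2 = lf.gains(0, [2e-8, 0, 0])
        assert np.allclose(g2, 2 * g1)

    def test_superposition_of_dipoles(self, coarse_bem_solution):
        d1 = Dipole([0, 0.02, 0.03], [1e-8, 0, 0])
        d2 = Dipole([0.01, -0.02, 0.04], [0, 1e-8, 1e-8])
        lf = leadfield_from_solution(coarse_bem_solution, [d1, d2],
                                     reference=None)
        v1 = lf.gains(0, d1.moment)
        v2 = lf.gains(1, d2.moment)
        combined = lf.matrix @ np.concatenate([d1.moment, d2.moment])
        assert np.allclose(combined, v1 + v2)

    def test_average_reference_sums_to_zero(self, coarse_bem_solution):
        d = Dipole([0.01, 0.01, 0.05], [0, 0, 1e-8])
        lf = leadfield_from_solution(coarse_bem_solution, [d], reference=None)
        v = lf.gains(0, d.moment)
        v = v - v.mean()
        assert abs(v.sum()) < 1e-12 * np.abs(v).max()

    def test_cpz_reference_zero_row(self, coarse_bem_solution, montage):
        d = Dipole([0.01, 0.01, 0.05], [0, 0, 1e-8])
        lf = leadfield_from_solution(coarse_bem_solution, [d], reference="CPz")
        assert np.allclose(lf.matrix[montage.index("CPz")], 0.0)

    def test_dipole_outside_brain_rejected(self, coarse_bem_solution):
        d = Dipole([0, 0, 0.09], [0, 0, 1e-8])
        with pytest.raises(ValueError):
            leadfield_from_solution(coarse_bem_solution, [d])

    def test_finite(self, coarse_bem_solution):
        d = Dipole([0.02, 0, 0.04], [1e-8, 1e-8, 0])
        lf = leadfield_from_solution(coarse_bem_solution, [d])
        assert np.all(np.isfinite(lf.matrix))


class TestSkullSmearing:
    def test_higher_skull_conductivity_concentrates_map(self):
        """Raising skull conductivity toward brain value reduces smearing."""
        from mebci.forward.bem import bem_solution
        from mebci.forward.geometry import three_shell_mesh

        montage = standard_montage(scalp_radius=0.1)
        d = Dipole([0, 0, 0.05], [0, 0, 1e-8])
        spreads = []
        for skull in (0.0042, 0.33):
            mesh = three_shell_mesh(conductivities=(0.33, skull, 0.33),
                                    subdivisions=2)
            sol = bem_solution(mesh, montage)
            lf = leadfield_from_solution(sol, [d], reference=None)
            v = lf.gains(0, d.moment)
            v = np.abs(v - v.mean())
            v /= v.max()
            # spatial concentration: fraction of electrodes above half max
            spreads.append(np.mean(v > 0.5))
        assert spreads[1] <= spreads[0]


class TestLeadFieldContainer:
    def test_save_load_roundtrip(self, tmp_path, coarse_bem_solution):
        d = Dipole([0.01, 0, 0.05], [0, 0, 1e-8])
        lf = leadfield_from_solution(coarse_bem_solution, [d])
        path = tmp_path / "lf.tsv"
        lf.save(path)
        back = LeadField.load(path)
        assert np.allclose(back.matrix, lf.matrix)
        assert back.labels == lf.labels
        assert back.method == "bem"

    def test_invariants(self):
        with pytest.raises(ValueError):
            LeadField(np.full((2, 3), np.nan), ("a", "b"), "bem")
        with pytest.raises(ValueError):
            LeadField(np.zeros((2, 4)), ("a", "b"), "bem")


class TestPlaceDipole:
    def test_class_regions(self):
        assert place_dipole("mRS").region == "left_motor"
        assert place_dipole("mLS").region == "right_motor"
        assert place_dipole("mRB").region == "frontal"
        assert place_dipole("mFB").region == "frontal"

    def test_radial_orientation(self):
        d = place_dipole("mRS")
        u = d.position / np.linalg.norm(d.position)
        m = d.moment / np.linalg.norm(d.moment)
        assert np.allclose(u, m)

    def test_unknown_label(self):
        with pytest.raises(KeyError, match="mXX"):
            place_dipole("mXX")


class TestProjectToScalp:
    def test_zero_source(self, coarse_bem_solution):
        d = place_dipole("mRB")
        lf = leadfield_from_solution(coarse_bem_solution, [d])
        eeg = project_to_scalp(np.zeros(100), lf, 0, d.moment)
        assert np.all(eeg == 0)

    def test_linearity(self, coarse_bem_solution):
        d = place_dipole("mRB")
        lf = leadfield_from_solution(coarse_bem_solution, [d])
        src = np.sin(np.linspace(0, 10, 200))
        e1 = project_to_scalp(src, lf, 0, d.moment)
        e2 = project_to_scalp(3 * src, lf, 0, d.moment)
        assert np.allclose(e2, 3 * e1)

    def test_reference_channel_zero(self, coarse_bem_solution, montage):
        d = place_dipole("mRB")
        lf = leadfield_from_solution(coarse_bem_solution, [d], reference="CPz")
        src = np.sin(np.linspace(0, 10, 200))
        eeg = project_to_scalp(src, lf, 0, d.moment)
        assert np.allclose(eeg[:, montage.index("CPz")], 0.0)

    def test_rms_calibration(self, coarse_bem_solution):
        d = place_dipole("mLS")
        lf = leadfield_from_solution(coarse_bem_solution, [d])
        src = np.sin(np.linspace(0, 50, 500))
        eeg = project_to_scalp(src, lf, 0, d.moment, target_rms=10.0)
        rms = np.sqrt(np.mean(eeg**2, axis=0))
        assert np.median(rms[rms > 1e-9]) == pytest.approx(10.0, rel=1e-6)
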