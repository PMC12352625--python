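import numpy as np
import pytest

from hemelink import structure_io as sio
from hemelink import synthetic_data as sd
from hemelink import trajectory_analysis as ta
from hemelink.errors import CriteriaError, ValidationError
from hemelink.trajectory_analysis import HBondCriteria, HBondMode, Trajectory

from conftest import random_rigid_motion


@pytest.fixture
def site_topology():
    structure, _ = sd.make_porphyrin(sd.PorphyrinSpec(fe_water=2.5, seed=1))
    return structure


@pytest.fixture
def two_water_topology():
    structure, _ = sd.make_porphyrin(sd.PorphyrinSpec(fe_water=2.5, seed=1))
    sd.add_water(structure, [0.0, -6.0, 0.0], resseq=302)
    return structure


def _fe_index(structure):
    return next(
        i for i, a in enumerate(structure.models[0]) if a.element == "FE"
    )


def _static_trajectory(structure, n_frames):
    base = structure.coords(0)
    return Trajectory(topology=structure, frames=[base.copy() for _ in range(n_frames)])


class TestTrajectoryType:
    def test_zero_frames_rejected(self, site_topology):
        with pytest.raises(ValidationError):
            Trajectory(topology=site_topology, frames=[])

    def test_mismatched_frame_shape_rejected(self, site_topology):
        with pytest.raises(ValidationError):
            Trajectory(
                topology=site_topology, frames=[np.zeros((3, 3))]
            )

    def test_from_multi_model_structure(self, site_topology, tmp_path):
        traj, _ = sd.make_trajectory(
            sd.TrajectorySpec(n_frames=4, seed=0), site_topology
        )
        stacked = sio.Structure(
            models=[
                [
                    sio.AtomRecord(
                        serial=a.serial, name=a.name, altloc=a.altloc,
                        resname=a.resname, chain=a.chain, resseq=a.resseq,
                        element=a.element, occupancy=a.occupancy,
                        bfactor=a.bfactor, pos=frame[i],
                    )
                    for i, a in enumerate(site_topology.models[0])
                ]
                for frame in traj.frames
            ],
            source_format="pdb",
        )
        p = tmp_path / "frames.pdb"
        sio.write_pdb(stacked, p)
        back = Trajectory.from_structure(sio.read_structure(p))
        assert back.n_frames == 4
        np.testing.assert_allclose(back.frames[2], traj.frames[2], atol=1e-3)


class TestWaterResidence:
    def test_constant_water(self, site_topology):
        traj = _static_trajectory(site_topology, 100)
        profile = ta.water_residence(traj, _fe_index(site_topology))
        assert profile.occupancy == 1.0
        assert profile.mean == pytest.approx(2.5, abs=1e-9)
        assert profile.sd == pytest.approx(0.0, abs=1e-12)

    def test_no_waters(self):
        structure, _ = sd.make_porphyrin(sd.PorphyrinSpec(fe_water=None))
        traj = _static_trajectory(structure, 10)
        profile = ta.water_residence(traj, _fe_index(structure))
        assert profile.occupancy == 0.0
        assert profile.mean is None
        assert profile.sd is None

    def test_gaussian_parameter_recovery(self, site_topology):
        mu, sigma, n = 3.3, 0.1, 2000
        traj, truth = sd.make_trajectory(
            sd.TrajectorySpec(
                n_frames=n, fe_water_distribution=((1.0, mu, sigma),), seed=21
            ),
            site_topology,
        )
        profile = ta.water_residence(traj, truth["fe"], cutoff=3.5)
        assert profile.mean == pytest.approx(mu, abs=3 * sigma / np.sqrt(n) + 3e-3)
        assert profile.sd == pytest.approx(sigma, rel=0.10)

    def test_occupancy_equals_exhaustive_count(self, site_topology):
        traj, truth = sd.make_trajectory(
            sd.TrajectorySpec(
                n_frames=500,
                fe_water_distribution=((0.5, 3.3, 0.3), (0.5, 4.0, 0.3)),
                seed=8,
            ),
            site_topology,
        )
        cutoff = 3.5
        profile = ta.water_residence(traj, truth["fe"], cutoff=cutoff)
        waters = [
            i
            for i, a in enumerate(site_topology.models[0])
            if a.resname == "HOH" and a.element == "O"
        ]
        count = 0
        for frame in traj.frames:
            dmin = min(
                np.linalg.norm(frame[w] - frame[truth["fe"]]) for w in waters
            )
            count += dmin <= cutoff
        assert profile.occupancy == pytest.approx(count / 500)
        assert 0.0 <= profile.occupancy <= 1.0

    def test_statistics_over_contributing_frames_only(self, site_topology):
        traj, truth = sd.make_trajectory(
            sd.TrajectorySpec(
                n_frames=1000,
                fe_water_distribution=((0.5, 3.0, 0.05), (0.5, 5.0, 0.05)),
                seed=5,
            ),
            site_topology,
        )
        profile = ta.water_residence(traj, truth["fe"], cutoff=3.5)
        assert profile.occupancy == pytest.approx(0.5, abs=0.06)
        assert profile.mean == pytest.approx(3.0, abs=0.02)  # far mode excluded
        all_frames = ta.water_residence(
            traj, truth["fe"], cutoff=3.5, all_frames_stats=True
        )
        assert all_frames.mean == pytest.approx(4.0, abs=0.1)

    def test_rigid_motion_invariance(self, site_topology):
        traj, truth = sd.make_trajectory(
            sd.TrajectorySpec(n_frames=200, seed=13), site_topology
        )
        rng = np.random.default_rng(99)
        moved_frames = []
        for frame in traj.frames:
            rot, trans = random_rigid_motion(rng)
            moved_frames.append(frame @ rot.T + trans)
        moved = Trajectory(topology=site_topology, frames=moved_frames)
        a = ta.water_residence(traj, truth["fe"])
        b = ta.water_residence(moved, truth["fe"])
        assert b.occupancy == a.occupancy
        assert b.mean == pytest.approx(a.mean, abs=1e-9)
        assert b.sd == pytest.approx(a.sd, abs=1e-9)


class TestDistanceSeries:
    def test_constant(self, site_topology):
        traj = _static_trajectory(site_topology, 50)
        fe = _fe_index(site_topology)
        water = next(
            i for i, a in enumerate(site_topology.models[0]) if a.resname == "HOH"
        )
        mean, sd, _ = ta.distance_series(traj, fe, water)
        assert mean == pytest.approx(2.5, abs=1e-9)
        assert sd == 0.0

    def test_two_frame_closed_form(self, site_topology):
        base = site_topology.coords(0)
        fe = _fe_index(site_topology)
        water = next(
            i for i, a in enumerate(site_topology.models[0]) if a.resname == "HOH"
        )
        f1, f2 = base.copy(), base.copy()
        f1[water] = f1[fe] + [0.0, 0.0, 2.0]
        f2[water] = f2[fe] + [0.0, 0.0, 4.0]
        traj = Trajectory(topology=site_topology, frames=[f1, f2])
        mean, sd, _ = ta.distance_series(traj, fe, water)
        assert mean == pytest.approx(3.0)
        assert sd == pytest.approx(np.sqrt(2.0))

    def test_gaussian_recovery(self, site_topology):
        mu, sigma, n = 2.7, 0.2, 1500
        traj, truth = sd.make_trajectory(
            sd.TrajectorySpec(
                n_frames=n, fe_water_distribution=((1.0, mu, sigma),), seed=77
            ),
            site_topology,
        )
        mean, sd_est, _ = ta.distance_series(traj, truth["fe"], truth["mix_water"])
        assert mean == pytest.approx(mu, abs=3 * sigma / np.sqrt(n))
        assert sd_est == pytest.approx(sigma, rel=0.10)


class TestHBondOccupancy:
    def _pair_trajectory(self, structure, da, angle_deg, n_frames=20):
        """Donor at origin, acceptor at distance da, hydrogen making the
        requested D-H...A angle."""
        base = structure.coords(0)
        donor, hydrogen, acceptor = 0, 1, 2
        frames = []
        for _ in range(n_frames):
            f = base.copy()
            f[donor] = [0.0, 0.0, 0.0]
            f[acceptor] = [da, 0.0, 0.0]
            # place H 1 Å from D such that angle D-H-A = angle_deg
            theta = np.radians(180.0 - angle_deg)
            f[hydrogen] = [np.cos(theta), np.sin(theta), 0.0]
            frames.append(f)
        return Trajectory(topology=structure, frames=frames), donor, hydrogen, acceptor

    def test_always_satisfied(self, site_topology):
        traj, d, h, a = self._pair_trajectory(site_topology, 2.8, 165.0)
        crit = HBondCriteria(mode=HBondMode.WITH_HYDROGENS)
        assert ta.hbond_occupancy(traj, d, [h], a, crit) == 1.0

    def test_bad_angle_never_satisfied(self, site_topology):
        traj, d, h, a = self._pair_trajectory(site_topology, 2.8, 90.0)
        crit = HBondCriteria(dha_min_deg=120.0, mode=HBondMode.WITH_HYDROGENS)
        assert ta.hbond_occupancy(traj, d, [h], a, crit) == 0.0

    def test_heavy_only_ignores_angle(self, site_topology):
        traj, d, h, a = self._pair_trajectory(site_topology, 2.8, 90.0)
        assert ta.hbond_occupancy(traj, d, [], a, HBondCriteria()) == 1.0

    def test_with_hydrogens_requires_hydrogens(self, site_topology):
        traj, d, h, a = self._pair_trajectory(site_topology, 2.8, 165.0)
        crit = HBondCriteria(mode=HBondMode.WITH_HYDROGENS)
        with pytest.raises(CriteriaError):
            ta.hbond_occupancy(traj, d, [], a, crit)

    def test_mixed_trajectory_equals_brute_force(self, two_water_topology):
        traj, truth = sd.make_trajectory(
            sd.TrajectorySpec(n_frames=400, hbond_satisfied_fraction=0.37, seed=9),
            two_water_topology,
        )
        crit = HBondCriteria(da_max=3.5)
        frac = ta.hbond_occupancy(
            traj, truth["hbond_donor"], [], truth["hbond_acceptor"], crit
        )
        # exhaustive frame-by-frame oracle
        count = sum(
            np.linalg.norm(
                frame[truth["hbond_donor"]] - frame[truth["hbond_acceptor"]]
            )
            <= 3.5
            for frame in traj.frames
        )
        assert frac == pytest.approx(count / 400)
        assert frac == pytest.approx(round(0.37 * 400) / 400)
        assert 0.0 <= frac <= 1.0

    def test_criteria_validation(self):
        with pytest.raises(ValidationError):
            HBondCriteria(da_max=-1.0)
        with pytest.raises(ValidationError):
            HBondCriteria(dha_min_deg=200.0)


class TestDetectModes:
    def _hist(self, values, bin_width=0.05):
        return ta._histogram(np.asarray(values, dtype=float), bin_width)

    def test_unimodal_gaussian(self):
        rng = np.random.default_rng(2)
        values = rng.normal(3.3, 0.1, size=3000)
        modes = ta.detect_modes(self._hist(values))
        assert len(modes) == 1
        assert modes[0] == pytest.approx(3.3, abs=0.05)

    def test_bimodal_mixture(self):
        rng = np.random.default_rng(3)
        values = np.concatenate(
            [rng.normal(2.6, 0.1, size=2000), rng.normal(2.9, 0.1, size=2000)]
        )
        modes = ta.detect_modes(self._hist(values))
        assert len(modes) == 2
        assert modes[0] == pytest.approx(2.6, abs=0.06)
        assert modes[1] == pytest.approx(2.9, abs=0.06)

    def test_single_bin_histogram(self):
        edges = np.array([2.0, 2.05])
        counts = np.array([17])
        assert ta.detect_modes((edges, counts)) == [pytest.approx(2.025)]

    def test_flat_histogram_weighted_centre(self):
        edges = np.arange(0.0, 1.05, 0.1)
        counts = np.full(10, 5)
        modes = ta.detect_modes((edges, counts), smoothing=1)
        assert len(modes) == 1
        assert modes[0] == pytest.approx(0.5, abs=0.06)

    def test_empty_histogram_raises(self):
        with pytest.raises(ValidationError):
            ta.detect_modes((np.array([]), np.array([])))

    def test_modes_collapse_at_small_separation(self):
        rng = np.random.default_rng(4)
        values = np.concatenate(
            [rng.normal(2.70, 0.1, size=3000), rng.normal(2.75, 0.1, size=3000)]
        )
        modes = ta.detect_modes(self._hist(values))
        assert len(modes) == 1


class TestGeneratorIntegration:
    def test_residence_profile_modes_on_bimodal_trajectory(self, site_topology):
        traj, truth = sd.make_trajectory(
            sd.TrajectorySpec(
                n_frames=4000,
                fe_water_distribution=((0.5, 2.6, 0.1), (0.5, 2.9, 0.1)),
                seed=6,
            ),
            site_topology,
        )
        profile = ta.water_residence(traj, truth["fe"], cutoff=3.5)
        assert len(profile.modes) == 2
        assert profile.modes[0] == pytest.approx(2.6, abs=0.06)
        assert profile.modes[1] == pytest.approx(2.9, abs=0.06)
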