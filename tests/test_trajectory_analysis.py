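"""Occupancy tracking, persistence filtering, endpoint tables and RMSD."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ifacekit.refdata import lifetimes_as_records
from ifacekit.specific_interactions import SpecificInteraction
from ifacekit.structure_model import ResidueKey, assign_protonation
from ifacekit.synthetic_data import (
    PlantSpec,
    ScheduleSpec,
    make_synthetic_trajectory,
    make_toy_complex,
)
from ifacekit.trajectory_analysis import (
    OccupancyRecord,
    Trajectory,
    ca_rmsd_series,
    endpoint_contact_table,
    persistence_filter,
    plain_rmsd,
    superposed_rmsd,
    track_interactions,
)


def _toy_trajectory(fractions, n_frames=10, seed=0, jitter=0.05, spec_seed=1):
    spec = PlantSpec.random(n_contacts=1, n_hbs=2, n_sbs=2, seed=spec_seed)
    s, ledger = make_toy_complex(spec)
    assign_protonation(s, {})
    traj, truth = make_synthetic_trajectory(
        s, ledger, ScheduleSpec(fractions, n_frames=n_frames,
                                jitter_sigma=jitter, seed=seed))
    return s, ledger, traj, truth


class TestOccupancy:
    def test_always_present_is_100_percent(self):
        _, ledger, traj, _ = _toy_trajectory({}, n_frames=10)
        records = track_interactions(traj)
        assert len(records) == len(ledger.interactions)
        assert all(r.lifetime_percent == 100.0 for r in records)

    def test_91_of_100_frames(self):
        """A planted 91% schedule over 100 frames reads back as 91%."""
        _, ledger, traj, truth = _toy_trajectory({0: 0.91}, n_frames=100)
        records = {r.key: r for r in track_interactions(traj)}
        key = ledger.interactions[0].pair_key()
        assert records[key].frames_present == 91
        assert records[key].lifetime_percent == pytest.approx(91.0)
        assert len(truth[key]) == 91

    def test_zero_fraction_never_detected(self):
        _, ledger, traj, _ = _toy_trajectory({0: 0.0}, n_frames=10)
        keys = {r.key for r in track_interactions(traj)}
        assert ledger.interactions[0].pair_key() not in keys

    def test_empty_trajectory_rejected(self, planted_complex):
        s, _ = planted_complex
        with pytest.raises(ValueError):
            Trajectory(s, np.empty((0, len(s.atoms), 3)))

    def test_occupancy_bounds(self):
        _, _, traj, _ = _toy_trajectory({0: 0.4, 1: 0.7}, n_frames=10)
        for r in track_interactions(traj):
            assert 0.0 < r.occupancy <= 1.0
            assert 0.0 <= r.lifetime_percent <= 100.0


class TestPersistenceFilter:
    def _records(self, percents):
        out = []
        for n, p in enumerate(percents):
            inter = SpecificInteraction(
                "HB", ResidueKey("A", n, "", "SER"),
                ResidueKey("B", 1000 + n, "", "ASN"), ("OG",), ("OD1",))
            out.append(OccupancyRecord(inter, int(p), 100))
        return out

    def test_strictly_greater_than_threshold(self):
        records = self._records([49, 50, 51])
        kept = persistence_filter(records, 50)
        assert [r.lifetime_percent for r in kept] == [51.0]

    def test_descending_lifetime_order(self):
        kept = persistence_filter(self._records([60, 90, 75]), 50)
        assert [r.lifetime_percent for r in kept] == [90.0, 75.0, 60.0]

    def test_threshold_bounds(self):
        with pytest.raises(ValueError):
            persistence_filter([], 101)
        with pytest.raises(ValueError):
            persistence_filter([], -1)

    @given(st.lists(st.integers(min_value=0, max_value=100), max_size=30),
           st.integers(min_value=0, max_value=100),
           st.integers(min_value=0, max_value=100))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_monotone_in_threshold(self, percents, t1, t2):
        """Raising the threshold never increases the survivor count."""
        lo, hi = sorted((t1, t2))
        records = self._records(percents)
        assert len(persistence_filter(records, hi)) <= \
            len(persistence_filter(records, lo))

    @given(st.lists(st.integers(min_value=0, max_value=100), max_size=30))
    @settings(deadline=None, max_examples=30, derandomize=True)
    def test_edge_thresholds(self, percents):
        records = self._records(percents)
        assert len(persistence_filter(records, 0)) == \
            sum(1 for p in percents if p > 0)
        assert persistence_filter(records, 100) == []

    def test_published_survivor_counts(self):
        """13 / 9 / 4 interactions outlive half the run in the three
        MD-simulated complexes."""
        for cid, expected in [(4, 13), (7, 9), (6, 4)]:
            records = lifetimes_as_records(cid)
            assert len(persistence_filter(records, 50)) == expected


class TestEndpointTable:
    def test_single_frame_equals_direct_contacts(self, planted_complex):
        from ifacekit.contact_analysis import close_contacts
        s, _ = planted_complex
        traj = Trajectory(s, s.coords[None, :, :])
        assert endpoint_contact_table(traj).pairs == close_contacts(s).pairs

    def test_final_frame_only(self):
        """Two trajectories identical except the final frame differ exactly
        as the final frames do."""
        s, ledger, traj, _ = _toy_trajectory({0: 1.0}, n_frames=10, seed=4)
        frames2 = traj.frames.copy()
        # displace one planted interaction's partner residue in the last frame
        b_res = ledger.interactions[0].residue_b
        idx = s.residues[b_res]
        frames2[-1, idx] += np.array([0.0, 20.0, 0.0])
        t2 = Trajectory(s, frames2)
        ep1 = endpoint_contact_table(traj)
        ep2 = endpoint_contact_table(t2)
        assert np.array_equal(traj.frames[:-1], t2.frames[:-1])
        assert len(ep2.pairs) < len(ep1.pairs)

    def test_planted_endpoint_count(self):
        spec = PlantSpec.random(n_contacts=7, n_hbs=0, n_sbs=0, seed=23)
        s, ledger = make_toy_complex(spec)
        assign_protonation(s, {})
        traj, _ = make_synthetic_trajectory(
            s, ledger, ScheduleSpec({}, n_frames=10, seed=1))
        assert len(endpoint_contact_table(traj).pairs) == 7


class TestRmsd:
    def test_reference_frame_is_zero(self):
        _, _, traj, _ = _toy_trajectory({}, n_frames=5)
        series = ca_rmsd_series(traj, reference=0)
        assert series.values[0] == pytest.approx(0.0, abs=1e-9)
        assert (series.values >= 0).all()

    def test_rigid_motion_invariance(self):
        """A rotated-and-translated copy superposes back to ~0 RMSD."""
        from scipy.spatial.transform import Rotation
        s, _, traj, _ = _toy_trajectory({}, n_frames=2)
        rot = Rotation.from_euler("xyz", [0.4, 1.1, -0.7]).as_matrix()
        moved = traj.frames[0] @ rot.T + np.array([10.0, -3.0, 6.0])
        t2 = Trajectory(s, np.stack([traj.frames[0], moved]))
        series = ca_rmsd_series(t2, reference=0, superpose=True)
        assert series.values[1] == pytest.approx(0.0, abs=1e-6)

    def test_hand_computed_five_atom_oracle(self):
        """Displacing atoms by known amounts gives sqrt(mean(d_i^2))."""
        ref = np.array([[0.0, 0, 0], [3, 0, 0], [6, 0, 0],
                        [0, 3, 0], [3, 3, 0]])
        disp = np.array([0.2, 0.0, 0.4, 0.1, 0.3])
        mob = ref.copy()
        mob[:, 0] += disp
        expected = float(np.sqrt((disp ** 2).mean()))
        assert plain_rmsd(mob, ref) == pytest.approx(expected)

    def test_superposed_never_exceeds_plain(self):
        rng = np.random.default_rng(8)
        ref = rng.normal(size=(12, 3))
        mob = ref + rng.normal(scale=0.4, size=(12, 3))
        assert superposed_rmsd(mob, ref) <= plain_rmsd(mob, ref) + 1e-12

    def test_reference_out_of_range(self):
        _, _, traj, _ = _toy_trajectory({}, n_frames=3)
        with pytest.raises(IndexError):
            ca_rmsd_series(traj, reference=3)


class TestScheduleRecovery:
    @pytest.mark.parametrize("jitter", [0.0, 0.1])
    def test_planted_schedule_recovered_exactly(self, jitter):
        """Occupancy schedules read back as exact frame counts, with and
        without coordinate jitter."""
        fracs = {0: 0.3, 1: 0.85, 2: 0.55, 3: 0.1}
        s, ledger, traj, truth = _toy_trajectory(
            fracs, n_frames=40, jitter=jitter, seed=6)
        records = {r.key: r for r in track_interactions(traj)}
        for i, frac in fracs.items():
            key = ledger.interactions[i].pair_key()
            expected = int(round(frac * 40))
            assert records[key].frames_present == expected
            assert sorted(truth[key]) == truth[key]
            assert len(truth[key]) == expected
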