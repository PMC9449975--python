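import numpy as np
import pytest

from bsapkit import synth_fixtures as sf
from bsapkit.adsorption import (
    MinDistanceSeries,
    SurvivalCurve,
    bai,
    contact_counts,
    fit_desorption,
    mean_residence_time,
    min_distance_series,
    residence_events,
    survival_from_contact_matrix,
    survival_probability,
)
from bsapkit.core_io import Frame, Trajectory, min_image_distance


class TestMinDistanceSeries:
    def test_static_molecule_constant_series(self, toy_protein):
        system, frame = toy_protein
        traj, _ = sf.make_adsorption_trajectory(
            system, frame, k_on=0.0, n_frames=5, seed=1, n_neutral=1
        )
        series = min_distance_series(traj, 0)
        assert len(series.d_min) == 5
        assert (series.d_min >= 0.6 - 1e-9).all()

    def test_matches_brute_force_all_pairs(self, adsorption_fixture):
        traj, _ = adsorption_fixture
        system = traj.system
        mol = system.buffer_molecules[0]
        series = min_distance_series(traj, mol.molecule_id)
        for fi in [0, 37, 150, 299]:
            frame = traj.frames[fi]
            best = min(
                min_image_distance(frame.coordinates[i], frame.coordinates[j], frame.box)
                for i in mol.atom_indices
                for j in system.protein_indices
            )
            assert series.d_min[fi] == pytest.approx(best, abs=1e-5)

    def test_periodic_image_approach_has_no_jump(self, toy_protein):
        """A molecule leaving through one box face approaches the protein's
        image: d_min falls smoothly instead of jumping."""
        system, frame = toy_protein
        box = np.diag([6.0, 6.0, 6.0])
        shift = -frame.coordinates.min(axis=0) + 0.3
        prot = frame.coordinates + shift
        n = system.n_atoms

        from bsapkit.core_io import (
            Atom,
            AtomGroup,
            BufferMolecule,
            MolecularSystem,
            Residue,
        )

        atoms = list(system.atoms) + [
            Atom(n, "N1", "N", len(system.residues), "HS0", "B", 0.155, AtomGroup.BUFFER_NEUTRAL)
        ]
        residues = list(system.residues) + [Residue(len(system.residues), "HS0", "B", n, n + 1)]
        full = MolecularSystem(atoms, residues, [BufferMolecule(0, 0, (n,))])
        frames = []
        xs = np.linspace(3.0, 5.9, 30)  # walks toward the +x face
        for i, x in enumerate(xs):
            coords = np.vstack([prot, [x, prot[0, 1], prot[0, 2]]])
            frames.append(Frame(coordinates=coords, box=box, time=float(i)))
        traj = Trajectory(system=full, frames=frames)
        d = min_distance_series(traj, 0).d_min
        steps = np.abs(np.diff(d))
        assert steps.max() < 0.2  # smooth: no box-sized discontinuity

    def test_unknown_molecule_id(self, adsorption_fixture):
        traj, _ = adsorption_fixture
        with pytest.raises(ValueError, match="no buffer molecule"):
            min_distance_series(traj, 999)


class TestResidenceEvents:
    def test_never_adsorbed_gives_empty_list(self):
        series = MinDistanceSeries(0, np.arange(5) * 10.0, np.full(5, 0.8))
        assert residence_events(series) == []

    def test_hand_enumerated_two_events(self):
        """[0.5, 0.3, 0.3, 0.5, 0.35, 0.5] at dt = 10 ps: events of 20 and 10 ps."""
        series = MinDistanceSeries(0, np.arange(6) * 10.0, [0.5, 0.3, 0.3, 0.5, 0.35, 0.5])
        events = residence_events(series, r_cut=0.4)
        assert [(e.start_frame, e.end_frame) for e in events] == [(1, 2), (4, 4)]
        assert [e.tau_r for e in events] == [20.0, 10.0]

    def test_boundary_value_counts_as_adsorbed(self):
        series = MinDistanceSeries(0, np.arange(3) * 10.0, [0.5, 0.4, 0.5])
        assert len(residence_events(series, r_cut=0.4)) == 1

    def test_translation_equivariance(self):
        d = np.array([0.5, 0.3, 0.5, 0.3, 0.3, 0.5])
        a = residence_events(MinDistanceSeries(0, np.arange(6) * 10.0, d))
        b = residence_events(MinDistanceSeries(0, 100.0 + np.arange(6) * 10.0, d))
        assert [(e.start_frame, e.end_frame) for e in a] == [
            (e.start_frame, e.end_frame) for e in b
        ]

    def test_durations_conserve_adsorbed_frames(self, adsorption_fixture):
        traj, _ = adsorption_fixture
        dt = traj.timestep
        for mol in traj.system.buffer_molecules:
            series = min_distance_series(traj, mol.molecule_id)
            events = residence_events(series)
            total = sum(e.tau_r for e in events)
            assert total == pytest.approx((series.d_min <= 0.4).sum() * dt)

    def test_matches_generator_ground_truth_exactly(self, adsorption_fixture):
        traj, truth = adsorption_fixture
        for mol in traj.system.buffer_molecules:
            series = min_distance_series(traj, mol.molecule_id)
            events = residence_events(series)
            expected = truth[mol.molecule_id]
            assert [(e.start_frame, e.end_frame, e.tau_r) for e in events] == [
                (e.start_frame, e.end_frame, e.tau_r) for e in expected
            ]


class TestSurvivalProbability:
    def test_permanently_adsorbed_stays_at_one(self, toy_protein):
        system, frame = toy_protein
        traj, _ = sf.make_adsorption_trajectory(
            system, frame, k_on=10.0, n_frames=30, seed=4, dwell_mean=1e9, start_bound=True
        )
        curve = survival_probability(traj, charge_state=0)
        np.testing.assert_allclose(curve.S, 1.0)

    def test_single_contact_single_origin_step_function(self):
        contacts = np.zeros((1, 10), dtype=bool)
        contacts[0, 0:4] = True  # lasts exactly 4 frames
        curve = survival_from_contact_matrix(contacts, timestep=10.0, multi_origin=False)
        assert (curve.S[:4] == 1.0).all()
        assert (curve.S[4:] == 0.0).all()

    def test_no_contacts_raises(self):
        with pytest.raises(ValueError, match="no contacts"):
            survival_from_contact_matrix(np.zeros((2, 5), dtype=bool), timestep=1.0)

    def test_monotone_nonincreasing_in_unit_interval(self, adsorption_fixture):
        traj, _ = adsorption_fixture
        curve = survival_probability(traj, charge_state=0, max_lag=100)
        assert (np.diff(curve.S) <= 1e-12).all()
        assert curve.S[0] == 1.0
        assert ((curve.S >= 0) & (curve.S <= 1)).all()

    def test_exponential_telegraph_matches_closed_form(self, toy_protein):
        """Exponential dwell of mean tau: multi-origin S(t) tracks exp(-t/tau)."""
        system, frame = toy_protein
        tau, dt = 100.0, 10.0
        traj, truth = sf.make_adsorption_trajectory(
            system, frame, k_on=0.05, n_frames=3000, seed=77, timestep=dt,
            dwell_mean=tau, n_neutral=20,
        )
        n_events = sum(len(v) for v in truth.values())
        assert n_events > 4000
        curve = survival_probability(traj, charge_state=0, max_lag=40)
        expected = np.exp(-curve.lag_times / tau)
        assert np.abs(curve.S - expected).max() < 0.03

    def test_multi_and_single_origin_agree_on_stationary_process(self, toy_protein):
        system, frame = toy_protein
        traj, _ = sf.make_adsorption_trajectory(
            system, frame, k_on=0.05, n_frames=2000, seed=5, dwell_mean=100.0,
            n_neutral=30, start_bound=True,
        )
        multi = survival_probability(traj, charge_state=0, max_lag=20)
        single = survival_probability(traj, charge_state=0, max_lag=20, multi_origin=False)
        assert np.abs(multi.S - single.S).max() < 0.2  # single origin: ~30 samples


class TestFitDesorption:
    def test_recovers_single_exponential(self):
        t = np.arange(0, 3000.0, 10.0)
        curve = sf.make_survival_curve(1.0, 2.0, 1.0, 0.1, 1.0, t)
        fit = fit_desorption(curve)
        # a pure exponential leaves one term unconstrained: check the
        # dominant term carries k = 2 / ns, mu = 1
        if fit.amplitude >= 0.5:
            dom_a, dom_k, dom_mu = fit.amplitude, fit.k1, fit.mu1
        else:
            dom_a, dom_k, dom_mu = 1 - fit.amplitude, fit.k2, fit.mu2
        assert dom_a == pytest.approx(1.0, abs=0.02)
        assert dom_k == pytest.approx(2.0, rel=0.02)
        assert dom_mu == pytest.approx(1.0, rel=0.02)

    def test_recovers_double_stretched_noiseless_within_1pct(self):
        t = np.arange(0, 4000.0, 5.0)
        true = dict(amplitude=0.6, k1=2.0, mu1=0.5, k2=0.5, mu2=0.8)
        curve = sf.make_survival_curve(true["amplitude"], true["k1"], true["mu1"],
                                       true["k2"], true["mu2"], t)
        fit = fit_desorption(curve)
        for name, expected in true.items():
            assert getattr(fit, name) == pytest.approx(expected, rel=0.01), name

    def test_noisy_curve_recovered_within_three_stderr(self):
        t = np.arange(0, 4000.0, 5.0)
        true = dict(amplitude=0.6, k1=2.0, mu1=0.5, k2=0.5, mu2=0.8)
        curve = sf.make_survival_curve(true["amplitude"], true["k1"], true["mu1"],
                                       true["k2"], true["mu2"], t, noise_sd=0.01, seed=13)
        fit = fit_desorption(curve)
        for name, expected in true.items():
            err = fit.stderr[name]
            assert abs(getattr(fit, name) - expected) < max(3 * err, 0.05 * expected), name

    def test_constant_curve_is_degenerate(self):
        curve = SurvivalCurve(np.arange(20.0), np.ones(20), n_origins=1)
        with pytest.raises(ValueError, match="no decay"):
            fit_desorption(curve)

    def test_too_few_points_rejected(self):
        curve = SurvivalCurve(np.arange(5.0), np.exp(-np.arange(5.0)), n_origins=1)
        with pytest.raises(ValueError, match="10"):
            fit_desorption(curve)

    def test_deterministic(self):
        t = np.arange(0, 2000.0, 10.0)
        curve = sf.make_survival_curve(0.5, 3.0, 0.7, 0.3, 0.4, t, noise_sd=0.01, seed=3)
        a, b = fit_desorption(curve), fit_desorption(curve)
        assert (a.amplitude, a.k1, a.mu1, a.k2, a.mu2) == (b.amplitude, b.k1, b.mu1, b.k2, b.mu2)


class TestContactCountsAndBai:
    def test_no_buffer_in_range_gives_zeros(self, toy_protein):
        system, frame = toy_protein
        traj, _ = sf.make_adsorption_trajectory(system, frame, k_on=0.0, n_frames=3, seed=0)
        counts = contact_counts(traj, charge_state=0)
        assert all(v == 0.0 for v in counts.values())

    def test_matches_brute_force_pair_count(self, adsorption_fixture):
        traj, _ = adsorption_fixture
        system = traj.system
        counts = contact_counts(traj, charge_state=None, cutoff=0.4)
        # brute force over a few frames and all residues
        check_frames = [0, 100, 299]
        brute = {r: 0.0 for r in counts}
        buf = system.buffer_indices()
        for fi in check_frames:
            frame = traj.frames[fi]
            for res_index in brute:
                res = system.residues[res_index]
                n = 0
                for i in range(res.atom_start, res.atom_stop):
                    for j in buf:
                        if min_image_distance(frame.coordinates[i], frame.coordinates[j], frame.box) <= 0.4:
                            n += 1
                brute[res_index] += n
        partial = {r: 0.0 for r in counts}
        for fi in check_frames:
            frame = traj.frames[fi]
            sub = Trajectory(system=system, frames=[Frame(coordinates=frame.coordinates, box=frame.box)])
            one = contact_counts(sub, charge_state=None, cutoff=0.4)
            for r in partial:
                partial[r] += one[r]
        for r in brute:
            assert partial[r] == pytest.approx(brute[r], abs=1e-9)

    def test_direct_count_single_frame(self, toy_protein):
        system, frame = toy_protein
        traj, _ = sf.make_adsorption_trajectory(
            system, frame, k_on=10.0, n_frames=1, seed=8, dwell_mean=1e9, start_bound=True
        )
        counts = contact_counts(traj, charge_state=0)
        frame0 = traj.frames[0]
        buf = traj.system.buffer_indices(0)
        expected_total = 0
        for i in traj.system.protein_indices:
            for j in buf:
                if min_image_distance(frame0.coordinates[i], frame0.coordinates[j], frame0.box) <= 0.4:
                    expected_total += 1
        assert sum(counts.values()) == pytest.approx(expected_total)
        assert expected_total > 0

    def test_bai_closed_forms(self):
        results = bai({0: {0: 10.0, 1: 5.0, 2: 1.0}})
        values = results[0].per_residue_bai
        assert values[0] == 0.0
        assert values[1] == pytest.approx(np.log(2))
        assert values[2] == pytest.approx(np.log(10))

    def test_bai_two_units_at_nmax_over_e_squared(self):
        n_max = 7.0
        results = bai({0: {0: n_max, 1: n_max * np.exp(-2)}})
        assert results[0].per_residue_bai[1] == pytest.approx(2.0)

    def test_nmax_shared_across_charge_states(self):
        results = bai({0: {0: 4.0}, 1: {0: 8.0}})
        assert results[0].n_max == results[1].n_max == 8.0
        assert results[1].per_residue_bai[0] == 0.0
        assert results[0].per_residue_bai[0] == pytest.approx(np.log(2))

    def test_scale_invariance_of_differences(self):
        a = bai({0: {0: 10.0, 1: 2.5}})[0].per_residue_bai
        b = bai({0: {0: 40.0, 1: 10.0}})[0].per_residue_bai
        assert a[1] - a[0] == pytest.approx(b[1] - b[0])

    def test_zero_count_residue_gets_inf_sentinel(self):
        results = bai({0: {0: 5.0, 1: 0.0}})
        assert np.isinf(results[0].per_residue_bai[1])
        assert 1 not in results[0].finite_bai

    def test_all_zero_counts_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            bai({0: {0: 0.0}})

    def test_mean_residence_time(self, adsorption_fixture):
        traj, truth = adsorption_fixture
        events = [e for evs in truth.values() for e in evs]
        assert mean_residence_time(events) == pytest.approx(
            np.mean([e.tau_r for e in events])
        )
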