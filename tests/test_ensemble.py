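"""Turn detection, NOE averaging, R_g/R_h, fragments and reweighting."""

import numpy as np
import pytest

import ctdkit as ck
from ctdkit.ensemble import (
    ConformerEnsemble,
    ConvergenceError,
    NOERestraint,
    ObservableSet,
    extract_fragments,
    maxent_reweight,
    noe_satisfaction,
    radius_of_gyration,
    rh_estimate,
    rh_power_law,
    turn_fraction,
)
from ctdkit.model import Atom, Chain, Frame, Residue, Topology, Trajectory, ValidationError

from conftest import grid_search_two_conformer


def _ensemble_from_coords(frames_coords, topology):
    frames = [Frame(coords=c, time_ps=float(k)) for k, c in enumerate(frames_coords)]
    return ConformerEnsemble(Trajectory(topology, frames))


def _backbone_chain(n_res, o_n_dist=None):
    """Four-residue-resolvable chain; optionally bend so O(1)-N(4) = o_n_dist."""
    chain, coords = ck.build_chain("S" * n_res, seed=0, geometry="extended")
    top = Topology([chain])
    if o_n_dist is not None:
        # move N of residue 4 to the requested distance from O of residue 1
        names = top.atom_names
        o1 = np.flatnonzero((top.atom_residue == 0) & (names == "O"))[0]
        n4 = np.flatnonzero((top.atom_residue == 3) & (names == "N"))[0]
        coords = coords.copy()
        coords[n4] = coords[o1] + [o_n_dist, 0.0, 0.0]
    return top, coords


class TestTurnFraction:
    def test_beta_turn_at_3A_counts(self):
        top, coords = _backbone_chain(6, o_n_dist=3.0)
        ens = _ensemble_from_coords([coords], top)
        frac, per_window = turn_fraction(ens, [("A", 1)])
        assert frac == 1.0
        assert per_window[("A", 1)] == 1.0

    def test_extended_chain_has_no_turns(self):
        top, coords = _backbone_chain(12)
        ens = _ensemble_from_coords([coords], top)
        quads = [("A", i) for i in range(1, 10)]
        frac, _ = turn_fraction(ens, quads)
        assert frac == 0.0

    def test_exactly_at_cutoff_is_not_a_turn(self):
        top, coords = _backbone_chain(6, o_n_dist=5.0)
        ens = _ensemble_from_coords([coords], top)
        frac, _ = turn_fraction(ens, [("A", 1)])
        assert frac == 0.0  # strict < 5 A

    def test_conformer_counted_once_despite_multiple_turn_windows(self):
        top, coords = _backbone_chain(8, o_n_dist=3.0)
        names = top.atom_names
        o2 = np.flatnonzero((top.atom_residue == 1) & (names == "O"))[0]
        n5 = np.flatnonzero((top.atom_residue == 4) & (names == "N"))[0]
        coords = coords.copy()
        coords[n5] = coords[o2] + [2.5, 0, 0]
        ens = _ensemble_from_coords([coords], top)
        frac, per_window = turn_fraction(ens, [("A", 1), ("A", 2)])
        assert frac == 1.0
        assert per_window[("A", 1)] == per_window[("A", 2)] == 1.0


def _two_atom_topology():
    chains = [Chain(chain_id="A", residues=[
        Residue(index=1, name3="SER", atoms=[Atom(name="HB1", element="H")]),
        Residue(index=2, name3="SER", atoms=[Atom(name="HB2", element="H")]),
    ])]
    return Topology(chains)


class TestNOESatisfaction:
    def _ensemble(self, distances):
        top = _two_atom_topology()
        frames = [np.array([[0.0, 0, 0], [d, 0, 0]]) for d in distances]
        return _ensemble_from_coords(frames, top)

    def _restraint(self, bound=5.65):
        return NOERestraint(res_a=1, atoms_a=("HB1",), res_b=2, atoms_b=("HB2",),
                            upper_bound_A=bound)

    def test_single_conformer_within_bound_matches(self):
        ens = self._ensemble([5.0])
        matched, report = noe_satisfaction(ens, [self._restraint()])
        assert matched == 1
        assert report["effective_A"].iloc[0] == pytest.approx(5.0)

    def test_r6_average_closed_form(self):
        # two equal-weight conformers at 4 and 8 A
        ens = self._ensemble([4.0, 8.0])
        matched, report = noe_satisfaction(ens, [self._restraint()], averaging="r6")
        expected = ((4.0 ** -6 + 8.0 ** -6) / 2) ** (-1 / 6)
        assert report["effective_A"].iloc[0] == pytest.approx(expected, abs=1e-3)
        assert matched == 1  # ~4.48 A <= 5.65 A

    def test_power_mean_bounds_for_random_weights(self, rng):
        dists = rng.uniform(3.0, 9.0, size=6)
        ens = self._ensemble(dists)
        for _ in range(10):
            w = rng.dirichlet(np.ones(6))
            for avg in ("r6", "r3"):
                _, report = noe_satisfaction(
                    ens, [self._restraint()], weights=w, averaging=avg)
                eff = report["effective_A"].iloc[0]
                assert dists.min() - 1e-9 <= eff <= dists.max() + 1e-9

    def test_min_averaging_is_ensemble_minimum(self):
        ens = self._ensemble([7.0, 6.2, 9.0])
        _, report = noe_satisfaction(ens, [self._restraint()], averaging="min")
        assert report["effective_A"].iloc[0] == pytest.approx(6.2)

    def test_unresolvable_selector_rejected(self):
        ens = self._ensemble([5.0])
        bad = NOERestraint(res_a=1, atoms_a=("HZ9",), res_b=2, atoms_b=("HB2",),
                           upper_bound_A=5.0)
        with pytest.raises(ValidationError):
            noe_satisfaction(ens, [bad])


class TestGeometryObservables:
    def test_rg_closed_forms(self):
        top = _two_atom_topology()
        frame = Frame(coords=np.array([[0.0, 0, 0], [2.0, 0, 0]]))
        assert radius_of_gyration(frame) == pytest.approx(1.0)
        single = Frame(coords=np.array([[3.0, 1.0, 2.0]]))
        assert radius_of_gyration(single) == 0.0

    def test_rg_invariant_under_rigid_motion(self, rng):
        coords = rng.normal(size=(10, 3)) * 4
        from scipy.spatial.transform import Rotation
        rot = Rotation.from_rotvec([1.0, 0.2, -0.5]).as_matrix()
        f1 = Frame(coords=coords)
        f2 = Frame(coords=coords @ rot.T + [10.0, -4.0, 2.0])
        assert radius_of_gyration(f1) == pytest.approx(radius_of_gyration(f2))

    def test_kirkwood_rh_two_particles_equals_twice_distance(self):
        chain, coords = ck.build_chain("GG", seed=0, geometry="extended")
        top = Topology([chain])
        frame = Frame(coords=coords)
        d = np.linalg.norm(
            coords[np.flatnonzero(top.atom_names == "CA")][0]
            - coords[np.flatnonzero(top.atom_names == "CA")][1])
        assert rh_estimate(frame, top) == pytest.approx(2 * d)

    def test_rh_scales_linearly_with_coordinates(self):
        chain, coords = ck.build_chain("SSSS", seed=3)
        top = Topology([chain])
        r1 = rh_estimate(Frame(coords=coords), top)
        r2 = rh_estimate(Frame(coords=coords * 2.5), top)
        assert r2 == pytest.approx(2.5 * r1)

    def test_rh_increases_under_uniform_expansion(self):
        chain, coords = ck.build_chain("SSSSSS", seed=4)
        top = Topology([chain])
        assert rh_estimate(Frame(coords=coords * 1.3), top) > rh_estimate(
            Frame(coords=coords), top)

    def test_rh_power_law_closed_forms(self):
        assert rh_power_law(1, coefficients=(4.0, 0.5)) == pytest.approx(4.0)
        assert rh_power_law(100, coefficients=(2.0, 0.5)) == pytest.approx(
            2 * rh_power_law(25, coefficients=(2.0, 0.5)))
        assert rh_power_law(100, "idp") > rh_power_law(50, "idp")


class TestExtractFragments:
    def test_26_repeat_chain_yields_24_windows_per_conformer(self):
        seq = ck.generate_heptad_sequence(26)
        ens = ck.random_conformer_ensemble(seq, n_conformers=2, seed=5)
        frags = extract_fragments(ens, motif="YSPTSPS", length=21)
        assert frags.n_conformers == 2 * 24
        assert frags.trajectory.topology.chains[0].sequence == "YSPTSPS" * 3
        assert frags.trajectory.topology.chains[0].residues[0].index == 1

    def test_seeded_subsampling_reproducible(self):
        seq = ck.generate_heptad_sequence(8)
        ens = ck.random_conformer_ensemble(seq, n_conformers=3, seed=5)
        a = extract_fragments(ens, max_fragments=7, seed=11)
        b = extract_fragments(ens, max_fragments=7, seed=11)
        assert a.n_conformers == b.n_conformers == 7
        for fa, fb in zip(a.trajectory.frames, b.trajectory.frames):
            assert np.array_equal(fa.coords, fb.coords)

    def test_missing_motif_rejected(self):
        ens = ck.random_conformer_ensemble("SSSSSSSSSSSSSSSSSSSSSSSS", 1, seed=0)
        with pytest.raises(ValidationError):
            extract_fragments(ens, motif="YSPTSPS", length=21)


class TestMaxentReweight:
    def _obs(self, predicted, experimental, sigma):
        return ObservableSet(predicted=np.asarray(predicted, float),
                             experimental=np.asarray(experimental, float),
                             sigma=np.asarray(sigma, float))

    def test_reference_weights_optimal_when_data_already_fit(self):
        y = [[1.0], [3.0]]
        obs = self._obs(y, [2.0], [0.5])  # uniform average = 2.0
        res = maxent_reweight(obs, theta=5.0)
        assert res.weights == pytest.approx([0.5, 0.5], abs=1e-6)
        assert res.skl < 1e-10
        assert res.chi2 < 1e-10

    def test_large_theta_returns_reference_weights(self):
        y = [[1.0], [3.0]]
        obs = self._obs(y, [2.9], [0.1])
        res = maxent_reweight(obs, theta=1e8)
        assert res.weights == pytest.approx([0.5, 0.5], abs=1e-4)
        assert res.skl < 1e-6

    def test_matches_grid_search_oracle_two_conformers(self):
        y = [[1.0], [3.0]]
        yexp, sigma, theta = [2.7], [0.2], 2.0
        res = maxent_reweight(self._obs(y, yexp, sigma), theta=theta)
        w_oracle, _ = grid_search_two_conformer(y, yexp, sigma, theta)
        assert res.weights == pytest.approx(w_oracle, abs=1e-4)

    def test_skl_decreases_and_chi2_increases_with_theta(self, rng):
        n = 12
        y = rng.normal(size=(n, 3)) * 2 + 5
        w_true = rng.dirichlet(np.ones(n))
        obs = self._obs(y, w_true @ y, [0.2, 0.2, 0.2])
        skls, chi2s = [], []
        for theta in (1.0, 10.0, 25.0, 100.0):
            res = maxent_reweight(obs, theta=theta)
            skls.append(res.skl)
            chi2s.append(res.chi2)
        assert all(a >= b - 1e-9 for a, b in zip(skls, skls[1:]))
        assert all(a <= b + 1e-9 for a, b in zip(chi2s, chi2s[1:]))

    def test_planted_weights_recovered_from_noise_free_observables(self):
        seq = ck.generate_heptad_sequence(4)
        ens = ck.random_conformer_ensemble(seq, n_conformers=8, seed=9)
        rng = np.random.default_rng(10)
        w_true = rng.dirichlet(np.ones(8) * 2)
        obs = ck.synth_observables(ens, w_true, noise_sd=0.0, sigma=0.1, seed=3,
                                   n_distances=6)
        res = maxent_reweight(obs, theta=0.001)
        fitted_avg = res.weights @ obs.predicted
        assert np.all(np.abs(fitted_avg - obs.experimental) < obs.sigma / 10)

    def test_invalid_theta_rejected(self):
        obs = self._obs([[1.0], [2.0]], [1.5], [0.1])
        with pytest.raises(ValidationError):
            maxent_reweight(obs, theta=0.0)
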