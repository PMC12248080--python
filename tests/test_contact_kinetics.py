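"""Contact detection, state calling, event kinetics and ensemble statistics."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.distance import cdist

from taildyn import synthetic_data as sd
from taildyn.contact_kinetics import (
    ContactTimeline,
    atomic_contacts,
    binding_stats,
    call_states,
    contact_statistics,
    detect_events,
    fraction_bound,
    radius_of_gyration,
)
from taildyn.trajectory_model import SelectionError, TrajectoryEnsemble


def _pair_ensemble(distance):
    atoms = pd.DataFrame(
        {
            "name": ["C1", "P1"],
            "element": ["C", "P"],
            "resid": [1, 1001],
            "resname": ["GLY", "DA"],
            "chain": ["A", "I"],
            "is_heavy": [True, True],
        }
    )
    coords = np.array([[[0.0, 0, 0], [distance, 0, 0]]])
    return TrajectoryEnsemble(
        coords, 1.0, atoms,
        selections={"tail": np.array([0]), "dna": np.array([1])},
        base_pairs={1001: 1},
    )


def _timeline(bools, stride=1.0):
    counts = np.asarray(bools, dtype=int)
    return ContactTimeline(
        counts=counts, residues=np.arange(1, counts.shape[0] + 1), stride_ns=stride
    )


class TestAtomicContacts:
    def test_cutoff_is_strict(self):
        assert atomic_contacts(_pair_ensemble(3.9), "tail", "dna").counts.sum() == 1
        assert atomic_contacts(_pair_ensemble(4.0), "tail", "dna").counts.sum() == 0

    def test_always_bound_toy_script(self):
        ens, _ = sd.gen_toy_nucleosome(binding_mode="always_bound", n_frames=30)
        tl = atomic_contacts(ens, "tail_A", "dna")
        assert tl.contacts.all()

    def test_agrees_with_all_pairs_oracle_on_random_frames(self, rng):
        n_tail, n_dna = 25, 25
        atoms = pd.DataFrame(
            {
                "name": ["X"] * 50,
                "element": ["C"] * n_tail + ["P"] * n_dna,
                "resid": list(range(1, n_tail + 1)) + list(range(1001, 1001 + n_dna)),
                "resname": ["GLY"] * n_tail + ["DA"] * n_dna,
                "chain": ["A"] * n_tail + ["I"] * n_dna,
                "is_heavy": [True] * 50,
            }
        )
        coords = rng.uniform(0, 15, (25, 50, 3))
        ens = TrajectoryEnsemble(
            coords, 1.0, atoms,
            selections={"tail": np.arange(n_tail), "dna": np.arange(n_tail, 50)},
        )
        tl = atomic_contacts(ens, "tail", "dna", track_base_pairs=False)
        for f in range(25):
            d = cdist(coords[f, :n_tail], coords[f, n_tail:])
            assert np.array_equal((d < 4.0).sum(axis=1), tl.counts[:, f])

    def test_hydrogens_excluded_and_empty_selection_rejected(self):
        ens = _pair_ensemble(3.0)
        ens.atoms.loc[1, "is_heavy"] = False
        ens.atoms.loc[1, "element"] = "H"
        with pytest.raises(SelectionError):
            atomic_contacts(ens, "tail", "dna")


class TestContactStatistics:
    def test_hand_computed_three_frame_toy(self):
        counts = np.array([[2, 0, 1], [0, 0, 0]])
        stats = contact_statistics([_timeline(counts)])
        means = stats["per_residue"]["mean_contacts"].to_numpy()
        assert np.allclose(means, [1.0, 0.0])

    def test_identical_copies_have_zero_sem(self):
        counts = np.array([[1, 1], [0, 1]])
        stats = contact_statistics([_timeline(counts), _timeline(counts)])
        assert np.allclose(stats["per_residue"]["sem"], 0.0)
        assert stats["n"] == 2

    def test_persistent_single_contact_heat_map(self):
        ens, _ = sd.gen_toy_nucleosome(
            binding_mode="always_bound", n_frames=20, bound_residues=[3]
        )
        tl = atomic_contacts(ens, "tail_A", "dna")
        stats = contact_statistics([tl])
        heat = stats["heat_map"]
        assert heat.loc[3].sum() > 0
        assert heat.drop(index=3).to_numpy().sum() == 0


class TestStates:
    def test_fraction_bound_values(self):
        tl = _timeline(np.ones((4, 2)))
        assert np.allclose(fraction_bound(tl), 1.0)
        counts = np.zeros((36, 1))
        counts[:2, 0] = 1
        assert fraction_bound(_timeline(counts))[0] == pytest.approx(2 / 36)
        assert fraction_bound(_timeline(np.zeros((3, 2))))[0] == 0.0

    def test_threshold_is_inclusive_no_more_than_10pc(self):
        counts = np.zeros((10, 2))
        counts[0, 0] = 1  # fraction exactly 0.10 -> unbound
        counts[:2, 1] = 1  # fraction 0.20 -> bound
        states = call_states(_timeline(counts), 0.10)
        assert not states[0] and states[1]

    def test_all_zero_contacts_is_single_unbound_segment(self):
        states = call_states(_timeline(np.zeros((5, 40))))
        ev = detect_events(states, 1.0)
        assert len(ev.events) == 1 and ev.events[0].state == "unbound"

    @settings(deadline=None, derandomize=True)
    @given(st.integers(0, 2**32 - 1))
    def test_raising_threshold_never_unbinds_frames(self, seed):
        rng = np.random.default_rng(seed)
        counts = (rng.random((10, 50)) < 0.2).astype(int)
        tl = _timeline(counts)
        low = call_states(tl, 0.10)
        high = call_states(tl, 0.30)
        # bound under the high threshold implies bound under the low one
        assert np.all(low[high])
        assert np.all(fraction_bound(tl) >= 0) and np.all(fraction_bound(tl) <= 1)


class TestEvents:
    def test_hand_enumerated_sequence(self):
        states = np.array([1, 1, 0, 0, 0, 1], dtype=bool)
        ev = detect_events(states, 1.0, min_duration_ns=50.0)
        spans = [(e.state, e.duration_ns) for e in ev.events]
        assert spans == [("bound", 2.0), ("unbound", 3.0), ("bound", 1.0)]
        assert ev.n_transitions == 2  # one unbinding + one binding
        assert ev.n_binding == 1 and ev.n_unbinding == 1
        assert ev.durations("bound", filtered=True).size == 0

    def test_all_bound_sequence(self):
        ev = detect_events(np.ones(100, dtype=bool), 1.0)
        assert len(ev.events) == 1 and ev.n_transitions == 0

    def test_durations_tile_the_timeline(self, rng):
        states = rng.random(500) < 0.5
        ev = detect_events(states, 2.0)
        total = sum(e.duration_ns for e in ev.events)
        assert total == pytest.approx(500 * 2.0)

    def test_filtered_residence_matches_truncated_geometric_expectation(self):
        """Post-filter bound dwell mean ~ 50 ns + full geometric mean."""
        tl = sd.gen_two_state_timeline(
            0.02, 0.01, 8, dt_ns=1.0, n_frames=600_000, seed=17
        )
        states = tl.ground_truth["states"]
        ev = detect_events(states, 1.0, min_duration_ns=50.0)
        kept = ev.durations("bound", filtered=True)
        assert kept.size >= 500
        # independent oracle: run-length scan + memorylessness of the
        # geometric dwell law (E[X | X >= m] = m - 1 + E[X])
        runs, current, state = [], 0, states[0]
        for s in states:
            if s == state:
                current += 1
            else:
                if state:
                    runs.append(current)
                current, state = 1, s
        if state:
            runs.append(current)
        oracle = np.array([float(r) for r in runs if r >= 50])
        assert np.array_equal(np.sort(kept), np.sort(oracle))
        p = -math.expm1(-0.01)
        expected = 49 + 1 / p
        assert kept.mean() == pytest.approx(expected, rel=0.05)


class TestBindingStats:
    def test_hand_evaluated_kd_and_free_energy(self):
        states = np.array([True] * 1600 + [False] * 400)
        bs = binding_stats(states, temperature_K=310.0)
        assert bs.kd == pytest.approx(0.25)
        assert bs.dG0_kJ_per_mol == pytest.approx(-3.57, abs=0.005)

    def test_equal_counts_give_zero_free_energy(self):
        bs = binding_stats(np.array([True, False] * 10))
        assert bs.kd == 1.0 and bs.dG0_kJ_per_mol == 0.0

    def test_all_bound_is_undefined_kd_sentinel(self):
        bs = binding_stats(np.ones(50, dtype=bool))
        assert math.isnan(bs.kd) and math.isnan(bs.dG0_kJ_per_mol)
        assert bs.frames_bound == 50 and bs.frames_unbound == 0

    def test_generator_stationary_odds_recovered_within_3_se(self):
        tl = sd.gen_two_state_timeline(
            0.02, 0.01, 36, dt_ns=1.0, n_frames=300_000, seed=23
        )
        states = call_states(tl)
        bs = binding_stats(states)
        ev = detect_events(states, 1.0, min_duration_ns=0.0)
        n_indep = max(len(ev.events), 2)
        frac = states.mean()
        se = np.sqrt(frac * (1 - frac) / n_indep) * 3  # dwell-level SE, 3x
        assert abs(frac - 2 / 3) < 3 * se
        odds = (1 - frac) / frac
        assert abs(bs.kd - 0.5) < 3 * se / frac**2


class TestRadiusOfGyration:
    def _ens(self, coords, elements):
        n = coords.shape[1]
        atoms = pd.DataFrame(
            {
                "name": ["X"] * n,
                "element": elements,
                "resid": range(1, n + 1),
                "resname": ["GLY"] * n,
                "chain": ["A"] * n,
                "is_heavy": [True] * n,
            }
        )
        return TrajectoryEnsemble(
            coords, 1.0, atoms, selections={"all": np.arange(n)}
        )

    def test_coincident_atoms_give_zero(self):
        ens = self._ens(np.zeros((2, 3, 3)), ["C"] * 3)
        assert np.allclose(radius_of_gyration(ens, "all"), 0.0)

    def test_two_equal_masses_10A_apart(self):
        coords = np.array([[[0.0, 0, 0], [10.0, 0, 0]]])
        ens = self._ens(coords, ["C", "C"])
        assert radius_of_gyration(ens, "all")[0] == pytest.approx(5.0)

    def test_square_matches_direct_sum_oracle(self, rng):
        s = 3.0
        coords = np.array([[[0, 0, 0], [s, 0, 0], [s, s, 0], [0, s, 0]]], dtype=float)
        ens = self._ens(coords, ["C"] * 4)
        rg = radius_of_gyration(ens, "all")[0]
        assert rg == pytest.approx(s / math.sqrt(2))
        # direct-sum oracle with unequal masses
        elements = ["C", "N", "O", "P"]
        ens2 = self._ens(coords, elements)
        masses = np.array([12.011, 14.007, 15.999, 30.974])
        com = (coords[0] * masses[:, None]).sum(0) / masses.sum()
        oracle = math.sqrt(
            float((masses * ((coords[0] - com) ** 2).sum(1)).sum() / masses.sum())
        )
        assert radius_of_gyration(ens2, "all")[0] == pytest.approx(oracle)
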