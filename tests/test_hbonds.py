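"""Hydrogen-bond scheme calling, canonical checks and lifetime profiles."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from bzdna.fiber import pose_chi
from bzdna.geometry import Atom, Frame
from bzdna.hbonds import (
    SCHEMES,
    assign_scheme,
    candidate_distances,
    canonical_check,
    lifetime_profile,
    mirror_scheme,
    nonbonded_density,
)
from bzdna.synthetic import MarkovSpec, markov_timeline


class TestCandidateDistances:
    def test_posed_distance_recovered(self, mm_duplex, rng):
        """Hand-set N1_a-N6_b separation is reported for that scheme."""
        frame, topo = mm_duplex
        d = candidate_distances(frame, topo)
        n1a = frame.position("A", 8, "N1")
        n6b = frame.position("B", 8, "N6")
        assert d["N1...N6"] == pytest.approx(float(np.linalg.norm(n1a - n6b)), abs=1e-9)
        assert set(d) == set(SCHEMES)

    def test_strand_swap_mirrors_directional_schemes(self, mm_duplex):
        frame, topo = mm_duplex
        fwd = candidate_distances(frame, topo, (("A", 8), ("B", 8)))
        rev = candidate_distances(frame, topo, (("B", 8), ("A", 8)))
        for s in SCHEMES:
            assert rev[mirror_scheme(s)] == pytest.approx(fwd[s], abs=1e-12)

    def test_matches_bruteforce_pairwise_oracle(self, mm_duplex):
        frame, topo = mm_duplex
        d = candidate_distances(frame, topo)
        atoms = {"a": {}, "b": {}}
        for a in frame:
            if a.chain_id == "A" and a.residue_index == 8:
                atoms["a"][a.name] = a.position
            if a.chain_id == "B" and a.residue_index == 8:
                atoms["b"][a.name] = a.position
        for scheme in SCHEMES:
            x, y = scheme.split("...")
            want = np.sqrt(((atoms["a"][x] - atoms["b"][y]) ** 2).sum())
            assert d[scheme] == pytest.approx(want, abs=1e-12)

    def test_missing_atom_errors(self, wc_duplex):
        frame, topo = wc_duplex
        with pytest.raises(KeyError):
            candidate_distances(frame, topo, (("A", 1), ("B", 15)))  # C has no N9/N6


class TestAssignScheme:
    def test_single_bonded_distance_wins(self):
        d = dict.fromkeys(SCHEMES, 6.0)
        d["N1...N6"] = 2.8
        a = assign_scheme(d)
        assert a.scheme == "N1...N6" and not a.borderline

    def test_all_beyond_none_cutoff_is_none(self):
        a = assign_scheme(dict.fromkeys(SCHEMES, 6.0))
        assert a.scheme == "none" and not a.borderline

    def test_minimum_distance_tiebreak(self):
        d = dict.fromkeys(SCHEMES, 6.0)
        d["N1...N6"] = 2.9
        d["N3...N6"] = 2.8
        assert assign_scheme(d).scheme == "N3...N6"

    def test_gap_zone_is_borderline_none(self):
        d = dict.fromkeys(SCHEMES, 6.0)
        d["N6...N3"] = 3.7
        a = assign_scheme(d)
        assert a.scheme == "none" and a.borderline

    @given(st.lists(st.floats(1.0, 10.0), min_size=6, max_size=6))
    def test_total_function(self, vals):
        a = assign_scheme(dict(zip(SCHEMES, vals)))
        assert a.scheme in set(SCHEMES) | {"none"}


class TestCanonicalCheck:
    def test_fiber_duplex_all_retained_in_printed_range(self, wc_duplex):
        frame, topo = wc_duplex
        reports = canonical_check(frame, topo)
        assert len(reports) == 15
        for rep in reports:
            assert not rep.broken
            for dist in rep.distances.values():
                assert 2.5 <= dist <= 3.5

    def test_mismatch_pair_excluded_by_default(self, mm_duplex):
        frame, topo = mm_duplex
        reports = canonical_check(frame, topo)
        assert len(reports) == 14
        assert all(("A", 8) not in rep.pair for rep in reports)

    def test_rotated_base_breaks_pair(self, wc_duplex):
        frame, topo = wc_duplex
        res = ("A", 8)  # an A...T pair in the fixture
        rotated = pose_chi(frame, topo, res, (241.0 + 90.0) % 360.0)
        rep = canonical_check(rotated, topo, pairs=[(res, topo.pairing[res])])
        assert rep[0].broken

    def test_empty_pair_list(self, wc_duplex):
        frame, topo = wc_duplex
        assert canonical_check(frame, topo, pairs=[]) == []

    def test_non_wc_pair_rejected(self, mm_duplex):
        frame, topo = mm_duplex
        with pytest.raises(ValueError):
            canonical_check(frame, topo, pairs=[(("A", 8), ("B", 8))])


def brute_force_runs(timeline):
    """Independent linear scanner for maximal run lengths."""
    runs = {}
    i = 0
    while i < len(timeline):
        j = i
        while j < len(timeline) and timeline[j] == timeline[i]:
            j += 1
        runs.setdefault(timeline[i], []).append(j - i)
        i = j
    return runs


class TestLifetimeProfile:
    def test_hand_counted_example(self):
        prof = lifetime_profile(["A", "A", "B", "B", "B", "A"])
        assert prof.runs == {"A": [2, 1], "B": [3]}
        assert prof.mean_lifetime == {"A": 1.5, "B": 3.0}
        assert prof.occupancy == {"A": 0.5, "B": 0.5}

    def test_constant_timeline_single_run(self):
        prof = lifetime_profile(["X"] * 137)
        assert prof.runs == {"X": [137]}

    def test_empty_timeline_rejected(self):
        with pytest.raises(ValueError):
            lifetime_profile([])

    def test_matches_bruteforce_scanner_on_random_timeline(self, rng):
        timeline = [str(s) for s in rng.integers(0, 4, size=10_000)]
        prof = lifetime_profile(timeline)
        assert prof.runs == brute_force_runs(timeline)

    def test_occupancies_sum_to_one_and_runs_reconstruct(self, rng):
        timeline = [str(s) for s in rng.integers(0, 3, size=5000)]
        prof = lifetime_profile(timeline)
        assert sum(prof.occupancy.values()) == pytest.approx(1.0)
        total = sum(sum(r) for r in prof.runs.values())
        assert total == prof.total_frames == len(timeline)
        rebuilt = [lab for lab, n in prof.reconstruct_order() for _ in range(n)]
        assert rebuilt == timeline

    def test_markov_mean_lifetime_matches_geometric_law(self):
        """Self-transition p gives mean run length 1/(1-p) within 3 SE."""
        p = 0.9
        n = 100_000
        T = np.array([[p, 1 - p], [1 - p, p]])
        spec = MarkovSpec(states=["N1...N6", "none"], transition=T,
                          length=n, seed=42)
        timeline = markov_timeline(spec)
        prof = lifetime_profile(timeline)
        for state in spec.states:
            runs = np.array(prof.runs[state], dtype=float)
            mean = runs.mean()
            se = runs.std(ddof=1) / np.sqrt(len(runs))
            assert abs(mean - 1.0 / (1 - p)) < 3 * se


class TestNonbondedDensity:
    def _dist(self, val):
        return dict.fromkeys(SCHEMES, float(val))

    def test_no_frame_beyond_cutoff_gives_zero_grid(self):
        chi = np.array([[60.0, 240.0]] * 10)
        counts, _, _ = nonbonded_density(chi, [self._dist(3.0)] * 10)
        assert counts.sum() == 0

    def test_constructed_nonbonded_fraction_recovered(self, rng):
        n = 1000
        frac = 0.30
        chi = rng.uniform(0, 360, size=(n, 2))
        nb = rng.random(n) < frac
        dists = [self._dist(6.0 if b else 3.0) for b in nb]
        counts, _, _ = nonbonded_density(chi, dists)
        assert counts.sum() == nb.sum()

    def test_region_bounds_filter_mass(self):
        chi = np.array([[200.0, 200.0], [50.0, 50.0]])
        dists = [self._dist(6.0)] * 2
        counts, _, _ = nonbonded_density(
            chi, dists, region_bounds=((190, 340), (190, 340))
        )
        assert counts.sum() == 1

    def test_misaligned_inputs_rejected(self):
        with pytest.raises(ValueError, match="misaligned"):
            nonbonded_density(np.zeros((3, 2)), [self._dist(5)] * 2)
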