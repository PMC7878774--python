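"""Mismatch base-pairing scheme detection and lifetime analysis.

The A...A mismatch can hydrogen bond through six directional schemes,
labeled 'X...Y' where X is the acceptor atom on the first adenine of the
pair and Y on the second, with the amine N6 donating the proton:

    N1...N6, N6...N1, N3...N6, N6...N3, N7...N6, N6...N7

A frame with no donor...acceptor distance at or below the bonded cutoff
(default 3.5 A) carries the scheme 'none'; frames where every distance
exceeds the non-bonded cutoff (default 4.0 A) additionally count toward
the non-hydrogen-bonded density maps, while the 3.5-4.0 A gap zone is
'none' but flagged borderline and excluded from those maps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import DuplexTopology, Frame, ResidueId

__all__ = [
    "SCHEMES",
    "SchemeAssignment",
    "LifetimeProfile",
    "candidate_distances",
    "assign_scheme",
    "canonical_check",
    "lifetime_profile",
    "nonbonded_density",
    "mirror_scheme",
]

#: directional scheme order (also the tie-break order for exact distance ties)
SCHEMES = ("N1...N6", "N6...N1", "N3...N6", "N6...N3", "N7...N6", "N6...N7")

#: (atom on residue a, atom on residue b) per scheme
_SCHEME_ATOMS = {
    "N1...N6": ("N1", "N6"),
    "N6...N1": ("N6", "N1"),
    "N3...N6": ("N3", "N6"),
    "N6...N3": ("N6", "N3"),
    "N7...N6": ("N7", "N6"),
    "N6...N7": ("N6", "N7"),
}

BONDED_CUTOFF = 3.5
NONE_CUTOFF = 4.0

#: Watson-Crick donor...acceptor atom pairs, keyed by (purine, pyrimidine)
WC_PAIRS = {
    ("G", "C"): (("O6", "N4"), ("N1", "N3"), ("N2", "O2")),
    ("A", "T"): (("N6", "O4"), ("N1", "N3")),
}


def mirror_scheme(scheme: str) -> str:
    """Scheme label after relabeling strands a<->b ('none' is fixed)."""
    if scheme == "none":
        return scheme
    x, y = scheme.split("...")
    return f"{y}...{x}"


def candidate_distances(
    frame: Frame,
    topology: DuplexTopology,
    mismatch_pair: tuple[ResidueId, ResidueId] | None = None,
) -> dict[str, float]:
    """Donor...acceptor distance (A) for each of the six mismatch schemes."""
    if mismatch_pair is None:
        if not topology.mismatch_pairs:
            raise ValueError("topology has no mismatch pair")
        mismatch_pair = topology.mismatch_pairs[0]
    res_a, res_b = mismatch_pair
    out = {}
    for scheme, (atom_a, atom_b) in _SCHEME_ATOMS.items():
        pa = frame.position(res_a[0], res_a[1], atom_a)
        pb = frame.position(res_b[0], res_b[1], atom_b)
        out[scheme] = float(np.linalg.norm(pa - pb))
    return out


@dataclass
class SchemeAssignment:
    """Scheme call for one frame, with diagnostics."""

    scheme: str
    borderline: bool
    min_distance: float
    sub_cutoff: list[str] = field(default_factory=list)


def assign_scheme(
    distances: dict[str, float],
    bonded_cutoff: float = BONDED_CUTOFF,
    none_cutoff: float = NONE_CUTOFF,
) -> SchemeAssignment:
    """Call the pairing scheme of one frame from its six distances.

    The minimum distance at or below ``bonded_cutoff`` wins (ties broken
    by the fixed order of SCHEMES); 'none' otherwise. Frames whose minimum
    lies in the (bonded_cutoff, none_cutoff] gap are 'none' but flagged
    borderline, and are excluded from non-bonded density counts.
    """
    dmin = min(distances.values())
    sub = [s for s in SCHEMES if distances[s] <= bonded_cutoff]
    if sub:
        best = min(sub, key=lambda s: (distances[s], SCHEMES.index(s)))
        return SchemeAssignment(best, False, dmin, sub)
    return SchemeAssignment("none", dmin <= none_cutoff, dmin, [])


@dataclass
class PairReport:
    pair: tuple[ResidueId, ResidueId]
    distances: dict[str, float]
    broken: bool


def canonical_check(
    frame: Frame,
    topology: DuplexTopology,
    pairs: list[tuple[ResidueId, ResidueId]] | None = None,
    cutoff: float = BONDED_CUTOFF,
) -> list[PairReport]:
    """Watson-Crick donor...acceptor distances and retained/broken flags.

    A pair is broken if any of its WC distances exceeds ``cutoff``.
    Only canonical pairs may be passed; the mismatch pairs of the topology
    are excluded from the default pair list.
    """
    if pairs is None:
        pairs = [
            (a, topology.pairing[a])
            for a in topology.strand_a
            if not topology.is_mismatch(a, topology.pairing[a])
        ]
    reports = []
    for res_a, res_b in pairs:
        if topology.is_mismatch(res_a, res_b):
            raise ValueError(f"pair {res_a}/{res_b} is flagged non-canonical")
        base_a = topology.sequence[res_a]
        base_b = topology.sequence[res_b]
        if (base_a, base_b) in WC_PAIRS:
            atom_pairs = WC_PAIRS[(base_a, base_b)]
            ra, rb = res_a, res_b
        elif (base_b, base_a) in WC_PAIRS:
            atom_pairs = WC_PAIRS[(base_b, base_a)]
            ra, rb = res_b, res_a
        else:
            raise ValueError(
                f"pair {res_a}/{res_b} ({base_a}...{base_b}) is not a WC pair"
            )
        dists = {}
        for atom_a, atom_b in atom_pairs:
            pa = frame.position(ra[0], ra[1], atom_a)
            pb = frame.position(rb[0], rb[1], atom_b)
            dists[f"{atom_a}...{atom_b}"] = float(np.linalg.norm(pa - pb))
        reports.append(
            PairReport((res_a, res_b), dists, any(d > cutoff for d in dists.values()))
        )
    return reports


@dataclass
class LifetimeProfile:
    """Per-scheme maximal run lengths, mean lifetimes and occupancies."""

    runs: dict[str, list[int]]
    mean_lifetime: dict[str, float]
    occupancy: dict[str, float]
    total_frames: int

    def reconstruct_order(self) -> list[tuple[str, int]]:
        """(label, run length) segments in timeline order (set by caller)."""
        return self._segments

    _segments: list[tuple[str, int]] = field(default_factory=list, repr=False)


def lifetime_profile(timeline) -> LifetimeProfile:
    """Run-length lifetime profile of a scheme timeline.

    Runs are maximal contiguous segments of one label; the mean lifetime
    of a scheme is its mean run length (frames) and its occupancy the
    fraction of total frames it covers.
    """
    timeline = list(timeline)
    if not timeline:
        raise ValueError("empty timeline")
    segments: list[tuple[str, int]] = []
    current = timeline[0]
    length = 1
    for label in timeline[1:]:
        if label == current:
            length += 1
        else:
            segments.append((current, length))
            current, length = label, 1
    segments.append((current, length))

    runs: dict[str, list[int]] = {}
    for label, n in segments:
        runs.setdefault(label, []).append(n)
    total = len(timeline)
    mean = {s: float(np.mean(r)) for s, r in runs.items()}
    occ = {s: sum(r) / total for s, r in runs.items()}
    prof = LifetimeProfile(runs, mean, occ, total)
    prof._segments = segments
    return prof


def nonbonded_density(
    chi_pairs: np.ndarray,
    distances: list[dict[str, float]],
    region_bounds: tuple[tuple[float, float], tuple[float, float]] | None = None,
    binsize: float = 10.0,
    none_cutoff: float = NONE_CUTOFF,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Frequency grid of non-hydrogen-bonded frames over glycosyl space.

    Counts only frames where all six donor...acceptor distances exceed
    ``none_cutoff`` (default 4 A), binned over (chi_a, chi_b). With
    ``region_bounds`` ((lo_a, hi_a), (lo_b, hi_b)), frames outside the
    region are excluded. Returns (counts, edges_a, edges_b).
    """
    chi_pairs = np.asarray(chi_pairs, dtype=float).reshape(-1, 2) % 360.0
    if len(chi_pairs) != len(distances):
        raise ValueError(
            f"misaligned inputs: {len(chi_pairs)} chi pairs vs "
            f"{len(distances)} distance maps"
        )
    nonbonded = np.array(
        [all(d > none_cutoff for d in dmap.values()) for dmap in distances]
    )
    if region_bounds is None:
        lo_a, hi_a = 0.0, 360.0
        lo_b, hi_b = 0.0, 360.0
    else:
        (lo_a, hi_a), (lo_b, hi_b) = region_bounds
    in_region = (
        (chi_pairs[:, 0] >= lo_a)
        & (chi_pairs[:, 0] <= hi_a)
        & (chi_pairs[:, 1] >= lo_b)
        & (chi_pairs[:, 1] <= hi_b)
    )
    keep = chi_pairs[nonbonded & in_region]
    na = max(1, int(round((hi_a - lo_a) / binsize)))
    nb = max(1, int(round((hi_b - lo_b) / binsize)))
    edges_a = np.linspace(lo_a, hi_a, na + 1)
    edges_b = np.linspace(lo_b, hi_b, nb + 1)
    counts, _, _ = np.histogram2d(keep[:, 0], keep[:, 1], bins=[edges_a, edges_b])
    return counts, edges_a, edges_b
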