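"""Transient-event metrics at a duplex mismatch site.

Quantifies the events reported from visual trajectory inspection: base
flipping (pseudo-dihedral), extrusion toward the major or minor groove
(signed radial displacement), base-base stacking (centroid distance +
interplanar angle) and base-pair opening (via the canonical H-bond
check). The thresholds are declared defaults, not literature constants:
flip when the pseudo-dihedral deviates more than 90 deg from the closed
reference, extrusion beyond 2.0 A, stacking within 4.5 A and 30 deg.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fiber import base_ring_atoms
from .geometry import DuplexTopology, Frame, GeometryError, ResidueId, dihedral
from .hbonds import canonical_check

__all__ = [
    "EventRecord",
    "flip_metric",
    "extrusion_metric",
    "stacking_detect",
    "minor_groove_width",
    "FLIP_DEVIATION_DEG",
    "EXTRUSION_CUTOFF",
    "STACK_DIST_CUTOFF",
    "STACK_ANGLE_CUTOFF",
    "GROOVE_RADIUS_CORRECTION",
]

FLIP_DEVIATION_DEG = 90.0
EXTRUSION_CUTOFF = 2.0
STACK_DIST_CUTOFF = 4.5
STACK_ANGLE_CUTOFF = 30.0
GROOVE_RADIUS_CORRECTION = 5.8  # phosphate-radius correction, A
GROOVE_OFFSET = -3  # cross-strand P(i)...P(j-3) three-level stagger


@dataclass
class EventRecord:
    frame_index: int
    residue: ResidueId
    flip_pseudodihedral: float | None
    flipped: bool
    extrusion_distance: float | None
    extruded: bool
    stacked_with_partner: bool
    pair_open: bool


def _base_centroid(frame: Frame, topology: DuplexTopology, res: ResidueId):
    chain, num = res
    names = base_ring_atoms(topology.sequence[res])
    return np.mean([frame.position(chain, num, n) for n in names], axis=0)


def _pair_centroid(frame: Frame, topology: DuplexTopology, res: ResidueId):
    partner = topology.partner(res)
    return 0.5 * (
        _base_centroid(frame, topology, res) + _base_centroid(frame, topology, partner)
    )


def _strand_neighbors(topology: DuplexTopology, res: ResidueId):
    strand = topology.strand_a if res in topology.strand_a else topology.strand_b
    k = strand.index(res)
    prev_res = strand[k - 1] if k > 0 else None
    next_res = strand[k + 1] if k + 1 < len(strand) else None
    return prev_res, next_res


def flip_metric(
    frame: Frame,
    residue: ResidueId,
    topology: DuplexTopology,
    reference: float | None = None,
) -> tuple[float | None, bool]:
    """Base-flip pseudo-dihedral (deg) and flipped flag.

    Pseudo-dihedral through: centroid of the 5'-flanking base pair, the
    residue's P, its C1', and its base-ring centroid. ``reference`` is the
    closed-state value; when given, flipped = deviation > 90 deg. Returns
    (None, False) for residues without a 5'-flanking pair or phosphate.
    """
    prev_res, _ = _strand_neighbors(topology, residue)
    chain, num = residue
    if prev_res is None or not frame.has_atom(chain, num, "P"):
        return None, False
    anchor = _pair_centroid(frame, topology, prev_res)
    p = frame.position(chain, num, "P")
    c1 = frame.position(chain, num, "C1'")
    base = _base_centroid(frame, topology, residue)
    value = dihedral(anchor, p, c1, base)
    if reference is None:
        return value, False
    dev = (value - reference) % 360.0
    dev = dev - 360.0 if dev > 180.0 else dev
    return value, abs(dev) > FLIP_DEVIATION_DEG


def _local_axis(frame: Frame, topology: DuplexTopology, residue: ResidueId):
    """Least-squares line through the flanking base-pair centroids.

    Returns (point_on_axis, unit_direction). Uses up to two pairs on each
    side of the residue; raises GeometryError with fewer than two anchors.
    """
    strand = topology.strand_a if residue in topology.strand_a else topology.strand_b
    k = strand.index(residue)
    anchors = []
    for dk in (-2, -1, 1, 2):
        j = k + dk
        if 0 <= j < len(strand):
            anchors.append(_pair_centroid(frame, topology, strand[j]))
    if len(anchors) < 2:
        raise GeometryError(f"residue {residue}: too few flanking pairs for axis")
    pts = np.array(anchors)
    center = pts.mean(axis=0)
    _, _, vt = np.linalg.svd(pts - center)
    return center, vt[0]


def extrusion_metric(
    frame: Frame,
    residue: ResidueId,
    topology: DuplexTopology,
    reference: Frame | None = None,
) -> tuple[float, bool]:
    """Signed groove-ward displacement (A) of the residue's base centroid.

    With a closed-state ``reference`` frame, the value is the displacement
    of the base centroid from its reference position projected onto the
    major-groove direction of the flanking pairs (+ = major groove,
    - = minor groove), so a scripted push of d Angstrom into a groove
    reads out as +/- d. Without a reference the radial excess of the
    centroid over the flanking-pair base radius is reported, signed by
    the groove half-space the centroid occupies. |value| > 2.0 A flags
    the residue extruded.
    """
    if reference is not None:
        centroid = _base_centroid(frame, topology, residue)
        centroid_ref = _base_centroid(reference, topology, residue)
        groove_dir = _flanking_groove_direction(reference, topology, residue)
        value = float(np.dot(centroid - centroid_ref, groove_dir))
        return value, abs(value) > EXTRUSION_CUTOFF

    center, axis = _local_axis(frame, topology, residue)
    strand = topology.strand_a if residue in topology.strand_a else topology.strand_b
    k = strand.index(residue)

    groove_dir = _flanking_groove_direction(frame, topology, residue, axis=axis)
    radii = []
    for dk in (-1, 1):
        j = k + dk
        if not (0 <= j < len(strand)):
            continue
        own = _base_centroid(frame, topology, strand[j])
        r = own - center
        radii.append(np.linalg.norm(r - np.dot(r, axis) * axis))
    r_ref = float(np.mean(radii))

    centroid = _base_centroid(frame, topology, residue)
    v = centroid - center
    v_perp = v - np.dot(v, axis) * axis
    radial_excess = float(np.linalg.norm(v_perp) - r_ref)
    sign = 1.0 if np.dot(centroid - center, groove_dir) >= 0 else -1.0
    value = sign * abs(radial_excess)
    return value, abs(value) > EXTRUSION_CUTOFF


def _flanking_groove_direction(
    frame: Frame, topology: DuplexTopology, residue: ResidueId, axis=None
):
    """Unit major-groove direction averaged over the flanking pairs.

    For each flanking pair the direction runs from the C1'-C1' midpoint
    through the pair's base centroid (the major-groove edge of the pair);
    with ``axis`` given the result is orthogonalized against it.
    """
    strand = topology.strand_a if residue in topology.strand_a else topology.strand_b
    k = strand.index(residue)
    dirs = []
    for dk in (-1, 1):
        j = k + dk
        if not (0 <= j < len(strand)):
            continue
        res_f = strand[j]
        partner = topology.partner(res_f)
        c1a = frame.position(res_f[0], res_f[1], "C1'")
        c1b = frame.position(partner[0], partner[1], "C1'")
        mid = 0.5 * (c1a + c1b)
        cen = _pair_centroid(frame, topology, res_f)
        d = cen - mid
        if axis is not None:
            d = d - np.dot(d, axis) * axis
        dirs.append(d / np.linalg.norm(d))
    if not dirs:
        raise GeometryError(f"residue {residue}: no flanking pair for groove direction")
    g = np.mean(dirs, axis=0)
    return g / np.linalg.norm(g)


def stacking_detect(
    frame: Frame,
    res_i: ResidueId,
    res_j: ResidueId,
    topology: DuplexTopology,
    dist_cutoff: float = STACK_DIST_CUTOFF,
    angle_cutoff: float = STACK_ANGLE_CUTOFF,
) -> bool:
    """True if the two bases stack: ring centroids within ``dist_cutoff``
    and interplanar angle at most ``angle_cutoff`` degrees."""

    def plane_normal(res):
        chain, num = res
        names = base_ring_atoms(topology.sequence[res])
        pts = np.array([frame.position(chain, num, n) for n in names])
        c = pts.mean(axis=0)
        _, _, vt = np.linalg.svd(pts - c)
        return c, vt[2]

    ci, ni = plane_normal(res_i)
    cj, nj = plane_normal(res_j)
    if np.linalg.norm(ci - cj) > dist_cutoff:
        return False
    cosang = abs(float(np.dot(ni, nj)))
    angle = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    return angle <= angle_cutoff


def minor_groove_width(
    frame: Frame,
    topology: DuplexTopology,
    correction: float = GROOVE_RADIUS_CORRECTION,
    offset: int = GROOVE_OFFSET,
) -> dict[ResidueId, float]:
    """Minor-groove width (A) per base-pair level.

    Cross-strand P(i)...P(j - offset) distances minus the phosphate-radius
    ``correction``, where j indexes the strand-b residue paired to
    strand-a residue i and the default offset realises the three-level
    minor-groove stagger.
    """
    if topology.n_pairs < 5:
        raise ValueError("duplex too short for groove analysis (<5 bp)")
    widths: dict[ResidueId, float] = {}
    n = topology.n_pairs
    for i_idx, res_a in enumerate(topology.strand_a):
        partner = topology.pairing[res_a]
        j_idx = topology.strand_b.index(partner)
        j_off = j_idx - offset
        if not (0 <= j_off < n):
            continue
        res_b = topology.strand_b[j_off]
        if not (
            frame.has_atom(res_a[0], res_a[1], "P")
            and frame.has_atom(res_b[0], res_b[1], "P")
        ):
            continue
        pa = frame.position(res_a[0], res_a[1], "P")
        pb = frame.position(res_b[0], res_b[1], "P")
        widths[res_a] = float(np.linalg.norm(pa - pb)) - correction
    return widths


def pair_open(
    frame: Frame, topology: DuplexTopology, pair: tuple[ResidueId, ResidueId]
) -> bool:
    """True if any WC donor...acceptor distance of a canonical pair > 3.5 A."""
    report = canonical_check(frame, topology, pairs=[pair])
    return report[0].broken
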