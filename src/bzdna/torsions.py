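"""Nucleic-acid backbone torsions, sugar pucker and conformer classification.

Backbone substates are called per base step from the rotamer wells of the
(epsilon_i, zeta_i, alpha_{i+1}, gamma_{i+1}) quadruple:

    BI  = (t,  g-, g-, g+)      BII = (g-, t,  g-, g+)
    BIII= (g-, g-, g-, g+)      ZI  = (g-, g+, g+, t)

Glycosyl angles are classified into +syn / anti / -syn regions of chi, and
sugar pucker by the pseudorotation phase (C2'-endo South vs C3'-endo
North). All well / region edges are module-level constants and can be
overridden per call.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import DuplexTopology, Frame, GeometryError, ResidueId, dihedral, wrap_angle

__all__ = [
    "TorsionRecord",
    "StepState",
    "compute_torsions",
    "compute_torsions_chain",
    "classify_well",
    "classify_step",
    "classify_glycosyl",
    "classify_pucker",
    "compute_pucker",
    "state_density",
    "STEP_LABELS",
]

#: rotamer well edges (degrees): g+ [0,120), t [120,240), g- [240,360)
WELL_EDGES = (120.0, 240.0)

#: step-state lookup, (eps, zeta, alpha, gamma) wells -> label
STEP_LABELS = {
    ("t", "g-", "g-", "g+"): "BI",
    ("g-", "t", "g-", "g+"): "BII",
    ("g-", "g-", "g-", "g+"): "BIII",
    ("g-", "g+", "g+", "t"): "ZI",
}

#: glycosyl class edges: +syn [20,100), anti [170,270), -syn [270,340)
GLYCOSYL_EDGES = {"+syn": (20.0, 100.0), "anti": (170.0, 270.0), "-syn": (270.0, 340.0)}

#: pseudorotation classes: South (C2'-endo) and North (C3'-endo)
SOUTH = (126.0, 198.0)
NORTH_HI = 342.0
NORTH_LO = 54.0


@dataclass
class TorsionRecord:
    """Backbone/glycosyl torsions of one residue in one frame (degrees).

    Chain-terminal torsions that need a neighbouring phosphate are None:
    alpha at the 5' end, epsilon/zeta at the 3' end.
    """

    residue: ResidueId
    frame_index: int
    alpha: float | None
    gamma: float
    epsilon: float | None
    zeta: float | None
    chi: float
    pucker_phase: float
    pucker_amplitude: float


@dataclass
class StepState:
    """Rotamer-well quadruple and substate label of base step i -> i+1."""

    step: tuple[ResidueId, ResidueId]
    wells: tuple[str, str, str, str]
    label: str


def classify_well(angle: float) -> str:
    """Rotamer well of a torsion: 'g+', 't' or 'g-'."""
    a = float(wrap_angle(angle))
    if a < WELL_EDGES[0]:
        return "g+"
    if a < WELL_EDGES[1]:
        return "t"
    return "g-"


def classify_step(wells: tuple[str, str, str, str]) -> str:
    """Label the (eps, zeta, alpha, gamma) well quadruple; 'other' if unnamed."""
    return STEP_LABELS.get(tuple(wells), "other")


def classify_glycosyl(chi: float, edges=None) -> str:
    """Glycosyl conformer class of chi: '+syn', 'anti', '-syn' or 'other'."""
    edges = GLYCOSYL_EDGES if edges is None else edges
    a = float(wrap_angle(chi))
    for label, (lo, hi) in edges.items():
        if lo <= a < hi:
            return label
    return "other"


def classify_pucker(phase: float) -> str:
    """'south' (C2'-endo), 'north' (C3'-endo) or 'other' from phase P."""
    p = float(wrap_angle(phase))
    if SOUTH[0] <= p < SOUTH[1]:
        return "south"
    if p >= NORTH_HI or p < NORTH_LO:
        return "north"
    return "other"


def _pos(frame: Frame, chain: str, resnum: int, name: str):
    try:
        return frame.position(chain, resnum, name)
    except KeyError:
        return None


def compute_pucker(frame: Frame, residue: ResidueId) -> tuple[float, float]:
    """Altona-Sundaralingam pseudorotation (phase P, amplitude) in degrees.

    Raises GeometryError for a broken or planar furanose ring.
    """
    chain, resnum = residue
    ring = ["C4'", "O4'", "C1'", "C2'", "C3'"]
    pos = [_pos(frame, chain, resnum, n) for n in ring]
    if any(p is None for p in pos):
        missing = [n for n, p in zip(ring, pos) if p is None]
        raise GeometryError(
            f"residue {chain}:{resnum}: sugar ring atom(s) missing: {missing}"
        )
    # nu_j: ring torsions, nu0 = C4'-O4'-C1'-C2' ... nu4 = C3'-C4'-O4'-C1'
    cyc = pos + pos  # wrap
    nus = []
    for j in range(5):
        t = dihedral(cyc[j], cyc[j + 1], cyc[j + 2], cyc[j + 3])
        nus.append(t - 360.0 if t > 180.0 else t)
    nu0, nu1, nu2, nu3, nu4 = nus
    s36, s72 = np.sin(np.radians(36.0)), np.sin(np.radians(72.0))
    y = (nu4 + nu1) - (nu3 + nu0)
    x = 2.0 * nu2 * (s36 + s72)
    amp_raw = np.hypot(x, y) / (2.0 * (s36 + s72))
    if amp_raw < 1e-6:
        raise GeometryError(f"residue {chain}:{resnum}: planar ring, pucker undefined")
    phase = float(np.degrees(np.arctan2(y, x)) % 360.0)
    amplitude = float(nu2 / np.cos(np.radians(phase)))
    return phase, amplitude


# chi atom sets: O4'-C1'-N9-C4 for purines, O4'-C1'-N1-C2 for pyrimidines
_CHI_ATOMS = {
    "pur": ("O4'", "C1'", "N9", "C4"),
    "pyr": ("O4'", "C1'", "N1", "C2"),
}


def _is_purine(resname: str) -> bool:
    return resname[-1] in ("A", "G")


def compute_torsions_chain(
    frame: Frame, chain_residues: list[ResidueId], frame_index: int = 0
) -> list[TorsionRecord]:
    """Torsion records for one strand's residues listed 5'->3'."""
    records = []
    for k, (chain, resnum) in enumerate(chain_residues):
        resname = frame.residue_name(chain, resnum)
        prev_res = chain_residues[k - 1] if k > 0 else None
        next_res = chain_residues[k + 1] if k + 1 < len(chain_residues) else None

        def req(res, name):
            p = _pos(frame, res[0], res[1], name)
            if p is None:
                raise GeometryError(
                    f"residue {res[0]}:{res[1]}: required atom {name} missing"
                )
            return p

        here = (chain, resnum)
        # alpha: O3'(i-1)-P-O5'-C5'; absent at the 5' terminus
        alpha = None
        if prev_res is not None:
            alpha = dihedral(
                req(prev_res, "O3'"), req(here, "P"), req(here, "O5'"), req(here, "C5'")
            )
        gamma = dihedral(
            req(here, "O5'"), req(here, "C5'"), req(here, "C4'"), req(here, "C3'")
        )
        epsilon = zeta = None
        if next_res is not None:
            epsilon = dihedral(
                req(here, "C4'"), req(here, "C3'"), req(here, "O3'"), req(next_res, "P")
            )
            zeta = dihedral(
                req(here, "C3'"), req(here, "O3'"), req(next_res, "P"),
                req(next_res, "O5'"),
            )
        kind = "pur" if _is_purine(resname) else "pyr"
        chi = dihedral(*(req(here, n) for n in _CHI_ATOMS[kind]))
        phase, amplitude = compute_pucker(frame, here)
        records.append(
            TorsionRecord(
                residue=here,
                frame_index=frame_index,
                alpha=alpha,
                gamma=gamma,
                epsilon=epsilon,
                zeta=zeta,
                chi=chi,
                pucker_phase=phase,
                pucker_amplitude=amplitude,
            )
        )
    return records


def compute_torsions(
    frame: Frame, topology: DuplexTopology, frame_index: int = 0
) -> list[TorsionRecord]:
    """Torsion records for both strands of a duplex (strand a then b)."""
    return compute_torsions_chain(
        frame, topology.strand_a, frame_index
    ) + compute_torsions_chain(frame, topology.strand_b, frame_index)


def step_states(records: list[TorsionRecord]) -> list[StepState]:
    """Step substates from consecutive records of one strand.

    Records must be in 5'->3' order for a single chain; the step i->i+1
    combines (eps, zeta) of residue i with (alpha, gamma) of residue i+1.
    """
    out = []
    for r1, r2 in zip(records, records[1:]):
        if r1.residue[0] != r2.residue[0]:
            continue
        if r1.epsilon is None or r1.zeta is None or r2.alpha is None:
            continue
        wells = (
            classify_well(r1.epsilon),
            classify_well(r1.zeta),
            classify_well(r2.alpha),
            classify_well(r2.gamma),
        )
        out.append(StepState(step=(r1.residue, r2.residue), wells=wells,
                             label=classify_step(wells)))
    return out


def state_density(
    angle_pairs: np.ndarray, binsize: float = 10.0
) -> tuple[np.ndarray, np.ndarray]:
    """Periodic 2D frequency histogram of an (N, 2) angle time series.

    Returns ``(freq, edges)`` where freq sums to 1 and edges are the common
    bin edges [0, binsize, ..., 360] for both axes. binsize must divide 360.
    """
    nbins = 360.0 / binsize
    if abs(nbins - round(nbins)) > 1e-9:
        raise ValueError(f"binsize {binsize} does not divide 360")
    nbins = int(round(nbins))
    pairs = wrap_angle(np.asarray(angle_pairs, dtype=float).reshape(-1, 2))
    edges = np.linspace(0.0, 360.0, nbins + 1)
    counts, _, _ = np.histogram2d(pairs[:, 0], pairs[:, 1], bins=[edges, edges])
    total = counts.sum()
    freq = counts / total if total > 0 else counts
    return freq, edges
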