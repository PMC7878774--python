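"""Synthetic stand-in for the MD engine: analytic free-energy surfaces with
biased Metropolis sampling (WHAM ground truth), Markov hydrogen-bond-scheme
timelines (lifetime ground truth), and scripted geometric trajectories
(event ground truth).

The default surface mimics the four favored glycosyl regions of an A...A
mismatch: I (+syn...anti), II (anti...anti), III (+syn...+syn) and
IV (anti...+syn), planted at (60, 240), (240, 240), (60, 60) and (240, 60)
degrees. Basin widths and depths are chosen so every minimum sits below
the 3 kcal/mol contour while the inter-basin saddles lie near 4.5-5
kcal/mol, and the direct diagonal transitions cross a higher ridge than
the horizontal/vertical ones. All generators are seed-deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fiber import BASE_TEMPLATES, base_ring_atoms, build_fiber_duplex
from .geometry import DuplexTopology, Frame, ResidueId, periodic_diff
from .hbonds import SCHEMES
from .wham import KB, UmbrellaWindow, bias_energy

__all__ = [
    "SurfaceSpec",
    "AnalyticSurface",
    "analytic_surface",
    "mc_sample_window",
    "sample_windows_batch",
    "MarkovSpec",
    "markov_timeline",
    "EventScript",
    "scripted_trajectory",
]

# ---------------------------------------------------------------------------
# analytic periodic surfaces


@dataclass
class SurfaceSpec:
    """Periodic Gaussian-mixture free-energy surface on [0,360)^2.

    ``depths`` are basin free energies (kcal/mol) relative to the global
    minimum; they are converted to mixture weights w = exp(-depth/kT).
    """

    centers: list[tuple[float, float]] = field(
        default_factory=lambda: [(60.0, 240.0), (240.0, 240.0),
                                 (60.0, 60.0), (240.0, 60.0)]
    )
    sigma: float | list[float] = 22.0  # deg
    depths: list[float] = field(default_factory=lambda: [0.0, 0.9, 1.4, 0.25])
    temperature: float = 300.0  # K
    labels: list[str] = field(default_factory=lambda: ["I", "II", "III", "IV"])

    def __post_init__(self):
        if not self.centers:
            raise ValueError("need at least one basin")
        sig = self.sigma if isinstance(self.sigma, (list, tuple)) else [
            self.sigma
        ] * len(self.centers)
        if any(s <= 0 for s in sig):
            raise ValueError("sigma must be > 0")
        self.sigma = list(map(float, sig))
        if len(self.depths) != len(self.centers) or len(self.sigma) != len(self.centers):
            raise ValueError("centers/sigma/depths length mismatch")


class AnalyticSurface:
    """Callable G(chi_a, chi_b) in kcal/mol, 360-periodic, min approx 0."""

    def __init__(self, spec: SurfaceSpec, offset: float = 0.0):
        self.spec = spec
        self.kt = KB * spec.temperature
        self.offset = float(offset)
        self._mu = np.array(spec.centers)  # (m, 2)
        self._sig = np.array(spec.sigma)
        self._w = np.exp(-np.array(spec.depths) / self.kt)

    def __call__(self, chi_a, chi_b):
        chi_a = np.asarray(chi_a, dtype=float)
        chi_b = np.asarray(chi_b, dtype=float)
        da = periodic_diff(chi_a[..., None], self._mu[:, 0])
        db = periodic_diff(chi_b[..., None], self._mu[:, 1])
        q = (np.asarray(da) ** 2 + np.asarray(db) ** 2) / (2.0 * self._sig**2)
        g = -self.kt * np.log((self._w * np.exp(-q)).sum(axis=-1)) - self.offset
        return g if g.ndim else float(g)

    def minima(self, grid_step: float = 0.5):
        """Dense-grid local minima locations and values (oracle)."""
        n = int(round(360.0 / grid_step))
        ax = grid_step * np.arange(n)
        A, B = np.meshgrid(ax, ax, indexing="ij")
        G = self(A, B)
        mins = []
        for si in (-1, 0, 1):
            for sj in (-1, 0, 1):
                if si == 0 and sj == 0:
                    continue
                mins.append(G <= np.roll(np.roll(G, si, axis=0), sj, axis=1))
        is_min = np.logical_and.reduce(mins)
        out = [
            ((float(ax[i]), float(ax[j])), float(G[i, j]))
            for i, j in zip(*np.nonzero(is_min))
        ]
        out.sort(key=lambda t: t[1])
        return out

    def normalized(self) -> "AnalyticSurface":
        """Copy shifted so the dense-grid global minimum is exactly 0."""
        gmin = self.minima()[0][1]
        return AnalyticSurface(self.spec, offset=self.offset + gmin)


def analytic_surface(spec: SurfaceSpec | None = None) -> AnalyticSurface:
    return AnalyticSurface(spec or SurfaceSpec())


# ---------------------------------------------------------------------------
# biased Metropolis sampling


def _metropolis(
    surface: AnalyticSurface,
    windows: list[UmbrellaWindow],
    n_samples: int,
    seed: int,
    step_size: float,
    burn_in: int | None,
    tune: bool,
    stride: int,
):
    """Vectorized Metropolis chains, one per window, stepping in lockstep.

    ``stride`` proposal moves are made per retained sample, emulating the
    MD practice of writing frames every ~1 ps while integrating at 2 fs:
    retained frames are effectively decorrelated under the restraint.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if step_size <= 0:
        raise ValueError("step size must be > 0")
    if stride < 1:
        raise ValueError("stride must be >= 1")
    rng = np.random.default_rng(seed)
    m = len(windows)
    centers = np.array([w.center for w in windows])  # (m, 2)
    ks = np.array([w.force_constant for w in windows])
    kt = surface.kt

    def energy(x):
        da = np.radians(periodic_diff(x[:, 0], centers[:, 0]))
        db = np.radians(periodic_diff(x[:, 1], centers[:, 1]))
        return surface(x[:, 0], x[:, 1]) + 0.5 * ks * (da * da + db * db)

    x = centers.copy()
    e = energy(x)
    steps = np.full(m, float(step_size))
    nb = (n_samples // 10) if burn_in is None else burn_in
    accepted = np.zeros(m)
    tried = 0
    out = np.empty((m, n_samples, 2))
    acc_total = np.zeros(m)
    n_total = (nb + n_samples) * stride
    for t in range(n_total):
        prop = (x + rng.normal(0.0, steps[:, None], size=(m, 2))) % 360.0
        ep = energy(prop)
        accept = rng.random(m) < np.exp(np.minimum(0.0, -(ep - e) / kt))
        x[accept] = prop[accept]
        e[accept] = ep[accept]
        accepted += accept
        tried += 1
        if t < nb * stride:
            if tune and tried == 50:
                rate = accepted / tried
                steps *= np.where(rate < 0.30, 0.7, 1.0) * np.where(
                    rate > 0.60, 1.4, 1.0
                )
                accepted[:] = 0.0
                tried = 0
        else:
            if t == nb * stride:
                accepted[:] = 0.0
                tried = 0
            k, rem = divmod(t - nb * stride, stride)
            if rem == stride - 1:
                out[:, k] = x
            acc_total += accept
    rate = acc_total / max(1, n_samples * stride)
    return out, steps, rate


def mc_sample_window(
    surface: AnalyticSurface,
    window: UmbrellaWindow,
    n: int,
    seed: int,
    step_size: float = 5.0,
    burn_in: int | None = None,
    tune: bool = True,
    stride: int = 10,
) -> UmbrellaWindow:
    """Metropolis samples from exp(-[G + U_bias]/kT) for one window.

    Returns a new UmbrellaWindow with ``n`` post-burn-in samples and frame
    indices 0..n-1; burn-in defaults to 10% of the chain length. The
    acceptance rate is stored on the result as ``acceptance_rate``.
    """
    out, _, rate = _metropolis(
        surface, [window], n, seed, step_size, burn_in, tune, stride
    )
    w = UmbrellaWindow(window.center, window.force_constant, out[0])
    w.acceptance_rate = float(rate[0])  # type: ignore[attr-defined]
    return w


def sample_windows_batch(
    surface: AnalyticSurface,
    windows: list[UmbrellaWindow],
    n: int,
    seed: int,
    step_size: float = 5.0,
    burn_in: int | None = None,
    tune: bool = True,
    stride: int = 10,
) -> list[UmbrellaWindow]:
    """Sample every window with independent chains advanced in lockstep."""
    out, _, rate = _metropolis(
        surface, windows, n, seed, step_size, burn_in, tune, stride
    )
    result = []
    for j, w in enumerate(windows):
        nw = UmbrellaWindow(w.center, w.force_constant, out[j])
        nw.acceptance_rate = float(rate[j])  # type: ignore[attr-defined]
        result.append(nw)
    return result


# ---------------------------------------------------------------------------
# Markov scheme timelines


@dataclass
class MarkovSpec:
    """Seeded Markov chain over hydrogen-bond scheme labels."""

    states: list[str] = field(default_factory=lambda: list(SCHEMES) + ["none"])
    transition: np.ndarray | None = None
    initial: str | None = None
    length: int = 10_000
    seed: int = 0

    def __post_init__(self):
        k = len(self.states)
        if self.transition is None:
            # mildly sticky default chain
            self.transition = np.full((k, k), 0.1 / max(1, k - 1))
            np.fill_diagonal(self.transition, 0.9)
        self.transition = np.asarray(self.transition, dtype=float)
        if self.transition.shape != (k, k):
            raise ValueError("transition matrix shape mismatch")
        if np.any(self.transition < 0):
            raise ValueError("negative transition probability")
        if np.max(np.abs(self.transition.sum(axis=1) - 1.0)) > 1e-12:
            raise ValueError("transition matrix rows must sum to 1")
        if self.initial is None:
            self.initial = self.states[0]
        if self.initial not in self.states:
            raise ValueError(f"initial state {self.initial!r} not in states")


def markov_timeline(spec: MarkovSpec) -> list[str]:
    """One seeded realization of the scheme chain."""
    rng = np.random.default_rng(spec.seed)
    k = len(spec.states)
    cum = np.cumsum(spec.transition, axis=1)
    idx = spec.states.index(spec.initial)
    out = np.empty(spec.length, dtype=int)
    u = rng.random(spec.length)
    for t in range(spec.length):
        out[t] = idx
        idx = int(np.searchsorted(cum[idx], u[t], side="right"))
        idx = min(idx, k - 1)
    return [spec.states[i] for i in out]


# ---------------------------------------------------------------------------
# scripted geometric trajectories


@dataclass
class EventScript:
    """One scripted rigid-body base event over an inclusive frame range.

    kind: 'flip' (rotate the base 180 deg about the glycosyl-perpendicular
    axis through C1'), 'extrude_major'/'extrude_minor' (translate the base
    along the +/- groove direction by ``amplitude`` A), 'open' (translate
    the base along the pair axis away from its partner), 'stack' (move the
    base over its intra-strand 5' neighbour).
    """

    kind: str
    residue: ResidueId
    start: int
    end: int
    amplitude: float = 4.0
    ramp: int = 2  # frames to ramp in/out

    def __post_init__(self):
        if self.kind not in {"flip", "extrude_major", "extrude_minor", "open", "stack"}:
            raise ValueError(f"unknown event kind {self.kind!r}")
        if self.end < self.start:
            raise ValueError("event end before start")


def _event_fraction(script: EventScript, t: int) -> float:
    """Ramp profile: 0 outside [start, end], 1 on the plateau."""
    if t < script.start or t > script.end:
        return 0.0
    r = max(1, script.ramp)
    up = min(1.0, (t - script.start + 1) / r)
    down = min(1.0, (script.end - t + 1) / r)
    return min(up, down)


def scripted_trajectory(
    sequence: str,
    scripts: list[EventScript],
    n_frames: int,
    mismatches: dict[int, str] | None = None,
) -> tuple[list[Frame], DuplexTopology, list[dict]]:
    """Multi-frame trajectory with scripted base events and ground truth.

    Builds the fiber duplex for ``sequence`` (with optional mismatches) and
    applies rigid-body base transformations interpolated over each script's
    frame range. Returns (frames, topology, ground_truth) where the ground
    truth lists one dict per event: kind, residue, start, end.
    """
    by_res: dict[ResidueId, list[EventScript]] = {}
    for s in scripts:
        by_res.setdefault(s.residue, []).append(s)
    for res, ss in by_res.items():
        ss.sort(key=lambda s: s.start)
        for s1, s2 in zip(ss, ss[1:]):
            if s2.start <= s1.end:
                raise ValueError(
                    f"overlapping events on residue {res}: "
                    f"[{s1.start},{s1.end}] and [{s2.start},{s2.end}]"
                )

    frame0, topo = build_fiber_duplex(sequence, mismatches=mismatches)
    for s in scripts:
        if s.residue not in topo.sequence:
            raise ValueError(f"scripted residue {s.residue} not in duplex")

    # geometric anchors per scripted residue, from the unperturbed duplex
    def base_atoms(res):
        letter = topo.sequence[res]
        return [n for n in BASE_TEMPLATES[letter] if n != "C1'"]

    def centroid(res):
        names = base_ring_atoms(topo.sequence[res])
        return np.mean([frame0.position(res[0], res[1], n) for n in names], axis=0)

    frames = []
    for t in range(n_frames):
        coords = frame0.coords.copy()
        for res, ss in by_res.items():
            for s in ss:
                f = _event_fraction(s, t)
                if f == 0.0:
                    continue
                idx = [frame0.atom_index(res[0], res[1], n) for n in base_atoms(res)]
                c1 = frame0.position(res[0], res[1], "C1'")
                cen = centroid(res)
                if s.kind == "flip":
                    # rotate about the in-plane axis through C1' perpendicular
                    # to the glycosyl direction => base swings out of the helix
                    partner = topo.partner(res)
                    pc = centroid(partner)
                    glyc = cen - c1
                    glyc /= np.linalg.norm(glyc)
                    ref = pc - c1
                    axis = np.cross(glyc, ref)
                    axis /= np.linalg.norm(axis)
                    ang = np.radians(180.0 * f)
                    K = np.array(
                        [
                            [0, -axis[2], axis[1]],
                            [axis[2], 0, -axis[0]],
                            [-axis[1], axis[0], 0],
                        ]
                    )
                    R = np.eye(3) + np.sin(ang) * K + (1 - np.cos(ang)) * (K @ K)
                    coords[idx] = (coords[idx] - c1) @ R.T + c1
                elif s.kind in ("extrude_major", "extrude_minor"):
                    d = _groove_direction(frame0, topo, res)
                    if s.kind == "extrude_minor":
                        d = -d
                    coords[idx] += f * s.amplitude * d
                elif s.kind == "open":
                    partner = topo.partner(res)
                    pc = centroid(partner)
                    d = cen - pc
                    d /= np.linalg.norm(d)
                    coords[idx] += f * s.amplitude * d
                elif s.kind == "stack":
                    strand = (
                        topo.strand_a if res in topo.strand_a else topo.strand_b
                    )
                    k = strand.index(res)
                    nb = strand[k - 1] if k > 0 else strand[k + 1]
                    target = centroid(nb) + np.array([0.0, 0.0, 3.4])
                    coords[idx] += f * (target - cen)
        frames.append(frame0.with_coords(coords, model_index=t + 1))

    truth = [
        {"kind": s.kind, "residue": s.residue, "start": s.start, "end": s.end,
         "amplitude": s.amplitude}
        for s in scripts
    ]
    return frames, topo, truth


def _groove_direction(frame: Frame, topo: DuplexTopology, res: ResidueId):
    """Unit major-groove direction at the residue (flanking-pair convention,
    shared with the event metrics so scripted pushes read out faithfully)."""
    from .events import _flanking_groove_direction

    return _flanking_groove_direction(frame, topo, res)
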