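"""2D periodic umbrella-sampling analysis: window grids, harmonic biases,
WHAM free-energy reconstruction, block-error estimation and basin/barrier
analysis.

The reaction coordinates are the two glycosyl torsions (chi_a, chi_b) of a
mismatched base pair, each periodic on [0, 360). Windows are restrained by
a harmonic bias U = k/2 [d(chi_a, c_a)^2 + d(chi_b, c_b)^2] with d the
minimal periodic image converted to radians (k in kcal/mol rad^2, as the
force constant is conventionally quoted). The coupled WHAM equations

    P(x) = sum_j n_j(x) / sum_j N_j exp[(F_j - U_j(x)) / kB T]
    exp(-F_j / kB T) = sum_x P(x) exp(-U_j(x) / kB T)

are iterated to self-consistency on the window free-energy constants F_j;
the PMF is -kB T ln P, min-normalized over sampled bins. Unsampled bins
are masked, never imputed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from heapq import heappop, heappush

import numpy as np
from scipy import sparse

from .geometry import periodic_diff

__all__ = [
    "KB",
    "UmbrellaWindow",
    "WhamConfig",
    "PMFGrid",
    "BasinReport",
    "WhamConvergenceError",
    "generate_windows",
    "bias_energy",
    "wham_2d",
    "block_error",
    "find_basins",
    "barrier_between",
    "line_barrier",
    "classify_transitions",
]

#: Boltzmann constant, kcal mol^-1 K^-1
KB = 1.9872041e-3

DEFAULT_FORCE_CONSTANT = 100.0  # kcal/mol rad^2
DEFAULT_SPACING = 10.0  # deg
DEFAULT_BIN_SIZE = 5.0  # deg
BASIN_THRESHOLD = 3.0  # kcal/mol


class WhamConvergenceError(RuntimeError):
    def __init__(self, iterations: int, residual: float, tolerance: float):
        self.iterations = iterations
        self.residual = residual
        super().__init__(
            f"WHAM did not converge in {iterations} iterations "
            f"(last max |dF| = {residual:.3e} kcal/mol, tolerance {tolerance:g})"
        )


@dataclass
class UmbrellaWindow:
    """One biased window: restraint center, force constant and samples."""

    center: tuple[float, float]  # (chi_a0, chi_b0) deg
    force_constant: float = DEFAULT_FORCE_CONSTANT  # kcal/mol rad^2
    samples: np.ndarray | None = None  # (n, 2) angles deg
    frame_indices: np.ndarray | None = None

    def __post_init__(self):
        if self.force_constant < 0:
            raise ValueError("force constant must be >= 0")
        self.center = (float(self.center[0]) % 360.0, float(self.center[1]) % 360.0)
        if self.samples is not None:
            self.samples = np.asarray(self.samples, dtype=float).reshape(-1, 2) % 360.0
            if self.frame_indices is None:
                self.frame_indices = np.arange(len(self.samples))
            else:
                self.frame_indices = np.asarray(self.frame_indices, dtype=int)
                if len(self.frame_indices) != len(self.samples):
                    raise ValueError("frame_indices/samples length mismatch")

    @property
    def n_samples(self) -> int:
        return 0 if self.samples is None else len(self.samples)


@dataclass
class WhamConfig:
    temperature: float = 300.0  # K
    bin_size: float = DEFAULT_BIN_SIZE  # deg
    tolerance: float = 1e-6  # kcal/mol, max |dF_j|
    max_iterations: int = 100_000
    check_monotone: bool = False

    def __post_init__(self):
        nbins = 360.0 / self.bin_size
        if abs(nbins - round(nbins)) > 1e-9:
            raise ValueError(f"bin size {self.bin_size} does not divide 360")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be > 0")

    @property
    def n_bins(self) -> int:
        return int(round(360.0 / self.bin_size))

    @property
    def kt(self) -> float:
        return KB * self.temperature


@dataclass
class PMFGrid:
    """Periodic free-energy surface on an n x n angular grid.

    ``values`` is in kcal/mol, min-normalized to 0 over sampled bins;
    unsampled bins hold +inf and are False in ``sampled``.
    """

    values: np.ndarray
    sampled: np.ndarray
    bin_edges: np.ndarray
    window_free_energies: np.ndarray
    converged: bool
    iterations: int
    temperature: float

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


def generate_windows(
    spacing_deg: float = DEFAULT_SPACING, k: float = DEFAULT_FORCE_CONSTANT
) -> list[UmbrellaWindow]:
    """Cartesian product of restraint centers {0, spacing, ..., 360-spacing}^2."""
    n = 360.0 / spacing_deg
    if abs(n - round(n)) > 1e-9:
        raise ValueError(f"spacing {spacing_deg} does not divide 360")
    n = int(round(n))
    centers = [i * spacing_deg for i in range(n)]
    return [UmbrellaWindow(center=(ca, cb), force_constant=k)
            for ca in centers for cb in centers]


def bias_energy(window: UmbrellaWindow, point) -> float:
    """Harmonic periodic restraint energy (kcal/mol) at an angle pair."""
    da = np.radians(periodic_diff(point[0], window.center[0]))
    db = np.radians(periodic_diff(point[1], window.center[1]))
    return float(0.5 * window.force_constant * (da * da + db * db))


def _bias_matrix(
    windows: list[UmbrellaWindow], config: WhamConfig, u_max_kt: float = 50.0
) -> sparse.csr_matrix:
    """Sparse Boltzmann bias weights w_jx = exp(-U_j(x)/kT) over flat bins.

    Entries with U > u_max_kt * kT underflow to exactly zero; for the stiff
    restraints used here this keeps ~3% of the grid per window.
    """
    nb = config.n_bins
    centers = 0.5 * config.bin_size + config.bin_size * np.arange(nb)
    kt = config.kt
    rows, cols, vals = [], [], []
    ca = np.array([w.center[0] for w in windows])
    cb = np.array([w.center[1] for w in windows])
    k_arr = np.array([w.force_constant for w in windows])
    for j in range(len(windows)):
        da = np.radians(periodic_diff(centers, ca[j]))
        db = np.radians(periodic_diff(centers, cb[j]))
        ua = 0.5 * k_arr[j] * da * da  # (nb,)
        ub = 0.5 * k_arr[j] * db * db
        u = ua[:, None] + ub[None, :]
        mask = u <= u_max_kt * kt
        idx = np.nonzero(mask.ravel())[0]
        rows.append(np.full(len(idx), j))
        cols.append(idx)
        vals.append(np.exp(-u.ravel()[idx] / kt))
    return sparse.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(len(windows), nb * nb),
    )


def _histogram(windows, config) -> tuple[np.ndarray, np.ndarray]:
    """Total bin counts c(x) (flat) and per-window sample counts N_j."""
    nb = config.n_bins
    c = np.zeros(nb * nb)
    n_j = np.zeros(len(windows))
    for j, w in enumerate(windows):
        if w.n_samples == 0:
            continue
        ia = np.floor(w.samples[:, 0] / config.bin_size).astype(int) % nb
        ib = np.floor(w.samples[:, 1] / config.bin_size).astype(int) % nb
        np.add.at(c, ia * nb + ib, 1.0)
        n_j[j] = w.n_samples
    return c, n_j


def _nll(g, n_j, c, W, kt):
    """WHAM negative log-likelihood (up to a constant), g_j = F_j/kT."""
    denom = W.T @ (n_j * np.exp(g))  # sum_j N_j e^{g_j} w_jx
    pos = c > 0
    return float(-(n_j * g).sum() - (c[pos] * np.log(c[pos] / denom[pos])).sum())


def wham_2d(
    windows: list[UmbrellaWindow],
    config: WhamConfig | None = None,
    *,
    bias: sparse.csr_matrix | None = None,
    sample_slice: slice | None = None,
) -> PMFGrid:
    """Solve the coupled 2D periodic WHAM equations for the PMF.

    ``bias`` lets callers reuse a precomputed bias matrix across repeated
    solves on the same window geometry (block errors); ``sample_slice``
    restricts every window to a frame-index slice without copying.

    Raises WhamConvergenceError if max |dF_j| does not fall below the
    configured tolerance within max_iterations.
    """
    config = config or WhamConfig()
    if sample_slice is not None:
        windows_used = [
            UmbrellaWindow(
                w.center,
                w.force_constant,
                None if w.samples is None else w.samples[sample_slice],
            )
            for w in windows
        ]
    else:
        windows_used = windows
    if not any(w.n_samples > 0 for w in windows_used):
        raise ValueError("no samples in any window")
    kt = config.kt
    W = bias if bias is not None else _bias_matrix(windows_used, config)
    c, n_j = _histogram(windows_used, config)

    g = np.zeros(len(windows_used))  # F_j / kT
    nll_prev = _nll(g, n_j, c, W, kt) if config.check_monotone else None
    converged = False
    it = 0
    residual = np.inf
    active = n_j > 0
    for it in range(1, config.max_iterations + 1):
        denom = W.T @ (n_j * np.exp(g))
        with np.errstate(divide="ignore", invalid="ignore"):
            p = np.where(denom > 0, c / denom, 0.0)
        p_sum = p.sum()
        p /= p_sum
        zeta = W @ p  # sum_x w_jx P(x) = exp(-F_j/kT)
        g_new = np.where(active, -np.log(np.maximum(zeta, 1e-300)), g)
        g_new = g_new - g_new[active][0]  # gauge fix
        residual = float(np.max(np.abs(g_new - g)[active]) * kt)
        g = g_new
        if config.check_monotone:
            nll = _nll(g, n_j, c, W, kt)
            if nll > nll_prev + 1e-7 * max(1.0, abs(nll_prev)):
                raise RuntimeError(
                    f"WHAM objective increased at iteration {it}: "
                    f"{nll_prev:.9g} -> {nll:.9g}"
                )
            nll_prev = nll
        if residual < config.tolerance:
            converged = True
            break
    if not converged:
        raise WhamConvergenceError(it, residual, config.tolerance)

    denom = W.T @ (n_j * np.exp(g))
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(denom > 0, c / denom, 0.0)
    p /= p.sum()
    nb = config.n_bins
    sampled = (c > 0).reshape(nb, nb)
    with np.errstate(divide="ignore"):
        pmf = np.where(p > 0, -kt * np.log(np.maximum(p, 1e-300)), np.inf)
    pmf = pmf.reshape(nb, nb)
    pmf[sampled] -= pmf[sampled].min()
    pmf[~sampled] = np.inf
    edges = np.linspace(0.0, 360.0, nb + 1)
    return PMFGrid(pmf, sampled, edges, g * kt, converged, it, config.temperature)


def block_error(
    windows: list[UmbrellaWindow],
    config: WhamConfig | None = None,
    blocks: list[slice] | None = None,
    mode: str = "disjoint-5",
    *,
    common_gauge: bool = False,
) -> tuple[np.ndarray, list[PMFGrid]]:
    """Per-bin standard deviation across block PMFs.

    ``mode='disjoint-5'`` partitions each window's samples into five equal
    consecutive blocks; ``mode='cumulative-3'`` nests them (first third,
    two thirds, all). Explicit ``blocks`` (frame-index slices) override the
    mode. Each block PMF is min-normalized before the std (set
    ``common_gauge=True`` to skip the per-block normalization instead).

    Returns (std grid with NaN outside commonly sampled bins, block PMFs).
    """
    config = config or WhamConfig()
    n = min(w.n_samples for w in windows if w.samples is not None)
    if blocks is None:
        if mode == "disjoint-5":
            edges = [round(i * n / 5) for i in range(6)]
            blocks = [slice(edges[i], edges[i + 1]) for i in range(5)]
        elif mode == "cumulative-3":
            blocks = [slice(0, round(n / 3)), slice(0, round(2 * n / 3)), slice(0, n)]
        else:
            raise ValueError(f"unknown block mode {mode!r}")
    for b in blocks:
        if all(len(range(*b.indices(w.n_samples))) == 0 for w in windows):
            raise ValueError(f"block {b} has zero samples in every window")

    bias = _bias_matrix(windows, config)
    grids = [wham_2d(windows, config, bias=bias, sample_slice=b) for b in blocks]
    stack = []
    for grid in grids:
        v = grid.values.copy()
        if common_gauge:
            v[grid.sampled] += 0.0  # keep the solver gauge
        v[~grid.sampled] = np.nan
        stack.append(v)
    stack = np.array(stack)
    ok = np.all(np.isfinite(stack), axis=0)
    std = np.full(grids[0].values.shape, np.nan)
    std[ok] = np.std(stack[:, ok], axis=0, ddof=0)
    return std, grids


@dataclass
class Basin:
    label: str
    bins: set[tuple[int, int]]
    minimum_bin: tuple[int, int]
    minimum_energy: float
    minimum_location: tuple[float, float]  # deg


@dataclass
class BasinReport:
    basins: list[Basin]
    threshold: float
    barriers: dict[tuple[str, str], float] = field(default_factory=dict)


def _neighbors8(i, j, n):
    for di in (-1, 0, 1):
        for dj in (-1, 0, 1):
            if di == 0 and dj == 0:
                continue
            yield ((i + di) % n, (j + dj) % n)


def find_basins(pmf: PMFGrid, threshold: float = BASIN_THRESHOLD) -> BasinReport:
    """Connected components (8-neighbor, periodic) of bins with PMF <= threshold."""
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    v = pmf.values
    n = v.shape[0]
    below = np.isfinite(v) & (v <= threshold)
    seen = np.zeros_like(below, dtype=bool)
    basins: list[Basin] = []
    centers = pmf.bin_centers
    for i0, j0 in zip(*np.nonzero(below)):
        if seen[i0, j0]:
            continue
        stack = [(int(i0), int(j0))]
        seen[i0, j0] = True
        comp = []
        while stack:
            i, j = stack.pop()
            comp.append((i, j))
            for ni, nj in _neighbors8(i, j, n):
                if below[ni, nj] and not seen[ni, nj]:
                    seen[ni, nj] = True
                    stack.append((ni, nj))
        mi, mj = min(comp, key=lambda ij: v[ij])
        basins.append(
            Basin(
                label="",
                bins=set(comp),
                minimum_bin=(mi, mj),
                minimum_energy=float(v[mi, mj]),
                minimum_location=(float(centers[mi]), float(centers[mj])),
            )
        )
    basins.sort(key=lambda b: b.minimum_energy)
    for idx, b in enumerate(basins):
        b.label = f"B{idx + 1}"
    return BasinReport(basins=basins, threshold=threshold)


def barrier_between(pmf: PMFGrid, basin_a: Basin, basin_b: Basin) -> float:
    """Minimax barrier (kcal/mol) between two basins over sampled bins.

    Minimizes, over periodic 8-neighbor paths from one basin minimum to
    the other that stay on sampled bins, the maximum PMF en route; the
    barrier is that value minus the higher of the two basin minima.
    Returns inf if the basins are disconnected through sampled bins.
    """
    if not basin_a.bins or not basin_b.bins:
        raise ValueError("empty basin")
    v = pmf.values
    n = v.shape[0]
    start, goal = basin_a.minimum_bin, basin_b.minimum_bin
    best = np.full(v.shape, np.inf)
    heap = [(v[start], start)]
    best[start] = v[start]
    while heap:
        h, (i, j) = heappop(heap)
        if (i, j) == goal:
            return float(h - max(basin_a.minimum_energy, basin_b.minimum_energy))
        if h > best[i, j]:
            continue
        for ni, nj in _neighbors8(i, j, n):
            if not pmf.sampled[ni, nj]:
                continue
            nh = max(h, v[ni, nj])
            if nh < best[ni, nj]:
                best[ni, nj] = nh
                heappush(heap, (nh, (ni, nj)))
    return float("inf")


def line_barrier(surface, a: tuple[float, float], b: tuple[float, float],
                 n_points: int = 721) -> float:
    """Direct-transition barrier along the straight periodic segment a -> b.

    ``surface`` is a callable G(chi_a, chi_b); the barrier is the maximum
    of G on the minimal-image straight path minus the higher endpoint
    value. This is the natural oracle for classifying direct transitions
    between minima as favorable or unfavorable.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    step = np.array(
        [periodic_diff(b[0], a[0]), periodic_diff(b[1], a[1])]
    )
    ts = np.linspace(0.0, 1.0, n_points)
    pts = (a[None, :] + ts[:, None] * step[None, :]) % 360.0
    vals = np.array([surface(p[0], p[1]) for p in pts])
    return float(vals.max() - max(vals[0], vals[-1]))


def classify_transitions(
    surface, centers: dict[str, tuple[float, float]]
) -> dict[tuple[str, str], float]:
    """Direct-path barriers between every pair of labeled minima."""
    out = {}
    labels = sorted(centers)
    for i, la in enumerate(labels):
        for lb in labels[i + 1:]:
            h = line_barrier(surface, centers[la], centers[lb])
            out[(la, lb)] = h
            out[(lb, la)] = h
    return out
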