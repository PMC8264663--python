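"""Steady-state diffusion problems with constant-value disk sources.

The physical setting is a square tissue patch discretized as an ``L x L``
pixel lattice. Circular sources (caricatures of blood-vessel cross sections)
hold the field at a constant value in ``(0, 1]``; everywhere else the field
diffuses with constant ``D`` and decays linearly at rate ``gamma``. The
domain boundary is absorbing: ghost pixels just outside the lattice are held
at zero. The stationary field solves, on the unit-spacing 5-point stencil,

    D * (sum of neighbor values - 4 u_i) - gamma * u_i = 0

at every non-source pixel, with ``u`` clamped to the disk value on source
pixels. The characteristic decay scale is the diffusion length
``l_D = sqrt(D / gamma)``.

Conventions (declared once, used everywhere):

* pixel centers sit at integer coordinates, 0-based, row-major;
* a pixel belongs to a disk iff the Euclidean distance from its center to
  the disk center is <= the disk radius;
* disk centers are sampled at integer coordinates; non-overlap is strict
  (center distance > 2 * radius), so disks never share pixels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

__all__ = [
    "GridSpec",
    "SourceDisk",
    "SourceConfiguration",
    "DatasetSplit",
    "diffusion_length",
    "sample_configuration",
    "rasterize",
    "solve_steady_state",
    "solve_dirichlet",
    "generate_dataset",
]

#: residual 2-norm the sparse solve must reach (asserted after every solve)
SOLVER_TOL = 1e-10

FORMAT_VERSION = 1


@dataclass(frozen=True)
class GridSpec:
    """Lattice size and physical constants of the diffusion problem.

    Defaults are the reference setting: a 100 x 100 lattice with D = 1
    pixel^2/s and gamma = 1/400 s^-1, giving diffusion length 20 pixels.
    """

    L: int = 100
    D: float = 1.0
    gamma: float = 1.0 / 400.0

    def __post_init__(self) -> None:
        if self.L < 8:
            raise ValueError(f"lattice size L must be >= 8, got {self.L}")
        if not (self.D > 0 and math.isfinite(self.D)):
            raise ValueError(f"diffusion constant D must be positive, got {self.D}")
        if not (self.gamma > 0 and math.isfinite(self.gamma)):
            raise ValueError(f"decay rate gamma must be positive, got {self.gamma}")

    @property
    def diffusion_length(self) -> float:
        return math.sqrt(self.D / self.gamma)


def diffusion_length(grid: GridSpec) -> float:
    """Characteristic decay distance ``sqrt(D / gamma)`` in pixels."""
    return grid.diffusion_length


@dataclass(frozen=True)
class SourceDisk:
    """A circular constant-value source: center (row, col), radius, value."""

    center_row: float
    center_col: float
    radius: float
    value: float

    def __post_init__(self) -> None:
        if not (self.radius > 0):
            raise ValueError("disk radius must be positive")
        if not (0.0 < self.value <= 1.0):
            raise ValueError(f"disk value must lie in (0, 1], got {self.value}")

    def contains(self, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
        """Membership mask: pixel-center distance to disk center <= radius."""
        return (rows - self.center_row) ** 2 + (
            cols - self.center_col
        ) ** 2 <= self.radius**2


@dataclass(frozen=True)
class SourceConfiguration:
    """An ordered set of non-overlapping, fully contained source disks."""

    disks: tuple[SourceDisk, ...]
    grid: GridSpec

    def __post_init__(self) -> None:
        object.__setattr__(self, "disks", tuple(self.disks))
        lo, hi = 0.0, self.grid.L - 1.0
        for d in self.disks:
            if (
                d.center_row - d.radius < lo
                or d.center_row + d.radius > hi
                or d.center_col - d.radius < lo
                or d.center_col + d.radius > hi
            ):
                raise ValueError(
                    f"disk at ({d.center_row}, {d.center_col}) r={d.radius} "
                    f"is not fully contained in [0, {hi}]^2"
                )
        for i, a in enumerate(self.disks):
            for b in self.disks[i + 1 :]:
                dist = math.hypot(
                    a.center_row - b.center_row, a.center_col - b.center_col
                )
                if dist <= a.radius + b.radius:
                    raise ValueError(
                        f"disks overlap or touch (center distance {dist:.3f} "
                        f"<= {a.radius + b.radius})"
                    )


def sample_configuration(
    rng: np.random.Generator | int,
    grid: GridSpec,
    radius: float = 5.0,
    n_disks: int = 2,
    max_attempts: int = 10_000,
) -> SourceConfiguration:
    """Draw a random source layout: disk 0 has value 1, the rest uniform (0, 1].

    Centers are drawn at integer coordinates uniformly over the admissible
    box [ceil(radius), floor(L - 1 - radius)] per axis; layouts whose centers
    come within ``2 * radius`` of each other are rejected and redrawn.

    Raises ``RuntimeError`` if no valid placement is found within
    ``max_attempts`` draws (geometrically impossible or near-impossible
    packings).
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    lo = math.ceil(radius)
    hi = math.floor(grid.L - 1 - radius)
    if hi < lo:
        raise ValueError(f"radius {radius} leaves no admissible centers on L={grid.L}")

    centers: list[tuple[int, int]] = []
    attempts = 0
    while len(centers) < n_disks:
        if attempts >= max_attempts:
            raise RuntimeError(
                f"no valid disk placement after {max_attempts} attempts "
                f"(L={grid.L}, radius={radius}, n_disks={n_disks})"
            )
        attempts += 1
        r = int(rng.integers(lo, hi + 1))
        c = int(rng.integers(lo, hi + 1))
        if all(math.hypot(r - rr, c - cc) > 2 * radius for rr, cc in centers):
            centers.append((r, c))

    disks = []
    for k, (r, c) in enumerate(centers):
        # disk 0 is the reference source at value 1; the rest are uniform (0, 1]
        value = 1.0 if k == 0 else float(1.0 - rng.random())
        disks.append(SourceDisk(r, c, radius, value))
    return SourceConfiguration(tuple(disks), grid)


def rasterize(config: SourceConfiguration) -> np.ndarray:
    """Paint the source layout onto the lattice: disk value inside, 0 outside."""
    L = config.grid.L
    rows, cols = np.mgrid[0:L, 0:L].astype(float)
    img = np.zeros((L, L), dtype=np.float64)
    for d in config.disks:
        img[d.contains(rows, cols)] = d.value
    return img


def _laplacian_system(
    source_mask: np.ndarray, source_values: np.ndarray, D: float, gamma: float
) -> tuple[sp.csr_matrix, np.ndarray]:
    """Assemble the stationary system on a lattice of any dimensionality.

    Non-source entries carry the discrete diffusion-decay balance with
    Dirichlet-0 ghost neighbors (absent neighbors simply drop out of the
    stencil sum); source entries are identity rows pinned to their value.
    """
    shape = source_mask.shape
    n = source_mask.size
    idx = np.arange(n).reshape(shape)
    free = ~source_mask.ravel()

    diag = np.where(free, -(2 * source_mask.ndim * D + gamma), 1.0)
    rows = [np.arange(n)]
    cols = [np.arange(n)]
    vals = [diag]

    for axis in range(source_mask.ndim):
        for shift in (-1, 1):
            sl_from = [slice(None)] * source_mask.ndim
            sl_to = [slice(None)] * source_mask.ndim
            if shift == 1:
                sl_from[axis] = slice(0, -1)
                sl_to[axis] = slice(1, None)
            else:
                sl_from[axis] = slice(1, None)
                sl_to[axis] = slice(0, -1)
            r = idx[tuple(sl_from)].ravel()
            c = idx[tuple(sl_to)].ravel()
            keep = free[r]  # only free pixels couple to neighbors
            rows.append(r[keep])
            cols.append(c[keep])
            vals.append(np.full(keep.sum(), D))

    A = sp.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n),
    )
    b = np.where(source_mask.ravel(), source_values.ravel(), 0.0)
    return A, b


def solve_dirichlet(
    source_mask: np.ndarray,
    source_values: np.ndarray,
    D: float,
    gamma: float,
) -> np.ndarray:
    """Solve the stationary field on an arbitrary-dimensional lattice.

    ``source_mask`` flags pixels pinned to ``source_values``; everywhere else
    the 2*ndim-point stencil with absorbing (zero) ghost boundaries applies.
    """
    A, b = _laplacian_system(source_mask, source_values, D, gamma)
    u = spla.spsolve(A.tocsc(), b)
    res = np.linalg.norm(A @ u - b)
    if not np.isfinite(u).all() or res > SOLVER_TOL * max(1.0, np.linalg.norm(b)):
        raise RuntimeError(f"sparse solve failed to converge (residual {res:.3e})")
    return u.reshape(source_mask.shape)


def solve_steady_state(
    input_image: np.ndarray, config: SourceConfiguration
) -> np.ndarray:
    """Stationary diffusion field for a rasterized source layout.

    The returned field equals the disk value on source pixels, solves the
    diffusion-decay balance elsewhere, and vanishes toward the absorbing
    boundary. By the discrete maximum principle all values lie in
    ``[0, max disk value]``.
    """
    L = config.grid.L
    if input_image.shape != (L, L):
        raise ValueError(f"input shape {input_image.shape} != grid ({L}, {L})")
    mask = input_image > 0
    return solve_dirichlet(mask, input_image, config.grid.D, config.grid.gamma)


@dataclass
class DatasetSplit:
    """Paired (source layout, stationary field) samples with a train/test split."""

    inputs: np.ndarray  # (n, L, L) float32
    targets: np.ndarray  # (n, L, L) float32
    train_idx: np.ndarray
    test_idx: np.ndarray
    meta: dict = field(default_factory=dict)

    @property
    def train(self) -> tuple[np.ndarray, np.ndarray]:
        return self.inputs[self.train_idx], self.targets[self.train_idx]

    @property
    def test(self) -> tuple[np.ndarray, np.ndarray]:
        return self.inputs[self.test_idx], self.targets[self.test_idx]

    def __len__(self) -> int:
        return len(self.inputs)


def generate_dataset(
    n_samples: int,
    rng_seed: int,
    grid: GridSpec | None = None,
    radius: float = 5.0,
    n_disks: int = 2,
    split_fraction: float = 0.8,
    progress: bool = False,
) -> DatasetSplit:
    """Generate ``n_samples`` independent (layout, field) pairs, split 80/20.

    Deterministic given ``rng_seed``. The split takes the first
    ``round(n * split_fraction)`` samples as training data; samples are
    i.i.d. so the ordering carries no structure.
    """
    if n_samples < 2:
        raise ValueError("need at least 2 samples to form a split")
    grid = grid or GridSpec()
    rng = np.random.default_rng(rng_seed)
    L = grid.L
    inputs = np.empty((n_samples, L, L), dtype=np.float32)
    targets = np.empty((n_samples, L, L), dtype=np.float32)

    iterator = range(n_samples)
    if progress:
        from tqdm import tqdm

        iterator = tqdm(iterator, desc="solving", unit="sample")
    for i in iterator:
        try:
            cfg = sample_configuration(rng, grid, radius=radius, n_disks=n_disks)
            x = rasterize(cfg)
            y = solve_steady_state(x, cfg)
        except Exception as exc:  # annotate which sample failed
            raise RuntimeError(f"dataset generation failed at sample {i}") from exc
        inputs[i] = x.astype(np.float32)
        targets[i] = y.astype(np.float32)

    n_train = int(round(n_samples * split_fraction))
    idx = np.arange(n_samples)
    meta = {
        "L": L,
        "D": grid.D,
        "gamma": grid.gamma,
        "radius": radius,
        "n_disks": n_disks,
        "n_samples": n_samples,
        "seed": rng_seed,
        "split_fraction": split_fraction,
        "format_version": FORMAT_VERSION,
    }
    return DatasetSplit(inputs, targets, idx[:n_train], idx[n_train:], meta)
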