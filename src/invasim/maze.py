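"""Maze environments: the 2D extracellular-matrix raster the agents move through.

The arena is a continuous world (default 800 x 800 world units) discretized
into a raster of square cells carrying non-negative *wall mass*.  A cell with
mass 0 is open; positive mass blocks motion and can be removed by proteolysis
(:func:`degrade`).  Conventions:

* origin at the lower-left, x rightward, y upward;
* cell ``(ix, iy)`` covers the half-open square
  ``[ix*cs, (ix+1)*cs) x [iy*cs, (iy+1)*cs)`` with ``cs = cell_size``;
* the domain boundary is impenetrable, non-degradable wall.

Mazes are loaded from single-channel images (luminance below half scale =
wall), from ``'#'``/``'.'`` text grids, or generated as random labyrinths of
thin, rounded walls with openings (:func:`generate_maze`).
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "Disc",
    "MazeGrid",
    "MazeGenParams",
    "load_maze",
    "generate_maze",
    "move_with_collision",
    "wall_normal",
    "degrade",
]


@dataclass(frozen=True)
class Disc:
    """A disc in world coordinates (used for the start and target zones)."""

    center: tuple[float, float]
    radius: float

    def contains(self, point) -> bool:
        dx = point[0] - self.center[0]
        dy = point[1] - self.center[1]
        return dx * dx + dy * dy <= self.radius * self.radius


@dataclass
class MazeGrid:
    """Wall-mass raster plus world geometry and the start/target discs."""

    wall_mass: np.ndarray  # shape (nx, ny), wall_mass[ix, iy] >= 0
    cell_size: float
    world_extent: tuple[float, float]
    start: Disc
    target: Disc

    def __post_init__(self):
        self.wall_mass = np.asarray(self.wall_mass, dtype=np.float64)
        if self.wall_mass.ndim != 2 or self.wall_mass.size == 0:
            raise ValueError("wall_mass must be a non-empty 2D raster")
        if np.any(self.wall_mass < 0):
            raise ValueError("wall_mass must be non-negative")
        wx, wy = self.world_extent
        if wx <= 0 or wy <= 0:
            raise ValueError("world_extent components must be positive")
        nx, ny = self.wall_mass.shape
        csx, csy = wx / nx, wy / ny
        if not math.isclose(csx, csy, rel_tol=1e-9):
            raise ValueError("cells must be square: world_extent/shape mismatch")
        if not math.isclose(csx, self.cell_size, rel_tol=1e-9):
            raise ValueError("raster shape x cell_size must equal world_extent")
        for disc, name in ((self.start, "start"), (self.target, "target")):
            cx, cy = disc.center
            if not (-disc.radius < cx < wx + disc.radius and -disc.radius < cy < wy + disc.radius):
                raise ValueError(f"{name} disc entirely outside the domain")

    # -- geometry queries ---------------------------------------------------

    @property
    def shape(self) -> tuple[int, int]:
        return self.wall_mass.shape

    def cell_of(self, point) -> tuple[int, int]:
        """Raster cell containing a world point (half-open cells)."""
        return (int(point[0] // self.cell_size), int(point[1] // self.cell_size))

    def cell_center(self, ix: int, iy: int) -> tuple[float, float]:
        return ((ix + 0.5) * self.cell_size, (iy + 0.5) * self.cell_size)

    def in_domain(self, point) -> bool:
        wx, wy = self.world_extent
        return 0.0 <= point[0] < wx and 0.0 <= point[1] < wy

    def blocked(self, point) -> bool:
        """True if the point lies in a wall cell or outside the domain."""
        if not self.in_domain(point):
            return True
        ix, iy = self.cell_of(point)
        return self.wall_mass[ix, iy] > 0.0

    def wall_fraction(self) -> float:
        return float(np.mean(self.wall_mass > 0))

    def total_mass(self) -> float:
        return float(self.wall_mass.sum())

    def copy(self) -> "MazeGrid":
        return MazeGrid(self.wall_mass.copy(), self.cell_size, self.world_extent,
                        self.start, self.target)

    def carve_disc(self, disc: Disc) -> None:
        """Open every cell intersecting the disc (conservative: centers within
        radius + half a cell diagonal)."""
        nx, ny = self.shape
        cs = self.cell_size
        pad = disc.radius + cs * math.sqrt(2.0) / 2.0
        cx, cy = disc.center
        ix0 = max(0, int((cx - pad) // cs))
        ix1 = min(nx - 1, int((cx + pad) // cs))
        iy0 = max(0, int((cy - pad) // cs))
        iy1 = min(ny - 1, int((cy + pad) // cs))
        for ix in range(ix0, ix1 + 1):
            for iy in range(iy0, iy1 + 1):
                ccx, ccy = self.cell_center(ix, iy)
                if (ccx - cx) ** 2 + (ccy - cy) ** 2 <= pad * pad:
                    self.wall_mass[ix, iy] = 0.0

    # -- serialization ------------------------------------------------------

    def to_text(self) -> str:
        """'#'/'.' grid, one row per line, first row = top of the world."""
        nx, ny = self.shape
        rows = []
        for iy in range(ny - 1, -1, -1):
            rows.append("".join("#" if self.wall_mass[ix, iy] > 0 else "."
                                for ix in range(nx)))
        return "\n".join(rows) + "\n"

    def to_pgm(self, path: str) -> None:
        """Plain-text PGM (P2): walls black, open space white, row 0 = top."""
        nx, ny = self.shape
        with open(path, "w") as fh:
            fh.write(f"P2\n{nx} {ny}\n255\n")
            for iy in range(ny - 1, -1, -1):
                fh.write(" ".join("0" if self.wall_mass[ix, iy] > 0 else "255"
                                  for ix in range(nx)) + "\n")


@dataclass
class MazeGenParams:
    """Parameters of the random labyrinth generator.

    Walls are thin bands that follow the median level-set of a correlated
    Gaussian field (giving winding, rounded barriers of typical spacing
    ``pore_scale``), interrupted by openings cut where a second, independent
    correlated field is high — a combination of blocking obstacles and open
    paths.

    wall_fraction : target fraction of wall cells in [0, 1), before the
        start/target discs are carved (band width is auto-tuned to hit it).
    pore_scale : correlation length of the wall field, world units; sets the
        typical corridor/obstacle spacing.
    wall_thickness : minimum wall feature width, world units (morphological
        closing scale for pinholes/specks).
    smoothing : kernel width used to round corners, world units.
    gap_fraction : fraction of the wall band removed as openings.
    gap_scale : correlation length of the opening field, world units; sets
        the typical width of openings.
    seed : generator seed (mazes are reproducible bit-exactly).
    """

    wall_fraction: float = 0.25
    pore_scale: float = 100.0
    wall_thickness: float = 8.0
    smoothing: float = 4.0
    gap_fraction: float = 0.25
    gap_scale: float = 50.0
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.wall_fraction < 1.0:
            raise ValueError("wall_fraction must be in [0, 1)")
        if self.pore_scale <= 0 or self.wall_thickness <= 0 or self.smoothing <= 0:
            raise ValueError("pore_scale, wall_thickness, smoothing must be > 0")
        if not 0.0 <= self.gap_fraction < 1.0 or self.gap_scale <= 0:
            raise ValueError("gap_fraction in [0,1) and gap_scale > 0 required")


# ---------------------------------------------------------------------------
# Loading


def _text_to_mask(text: str) -> np.ndarray:
    rows = [line for line in text.splitlines() if line.strip() != ""]
    if not rows:
        raise ValueError("empty maze text")
    width = len(rows[0])
    if any(len(r) != width for r in rows):
        raise ValueError("non-rectangular maze text grid")
    bad = set("".join(rows)) - {"#", "."}
    if bad:
        raise ValueError(f"invalid maze characters: {sorted(bad)}")
    ny, nx = len(rows), width
    mask = np.zeros((nx, ny), dtype=bool)
    for r, line in enumerate(rows):  # first text row = top of world
        iy = ny - 1 - r
        for c, ch in enumerate(line):
            mask[c, iy] = ch == "#"
    return mask


def _image_to_mask(path: str) -> np.ndarray:
    import imageio.v3 as iio

    img = np.asarray(iio.imread(path))
    if img.size == 0:
        raise ValueError("empty raster image")
    if img.ndim == 3:  # reduce to luminance
        img = img[..., :3].mean(axis=-1)
    img = img.astype(np.float64)
    if img.max() > 1.0:
        img = img / (255.0 if img.max() <= 255 else img.max())
    # img[row, col], row 0 = top; wall where luminance < 0.5 full scale
    wall_rc = img < 0.5
    ny, nx = wall_rc.shape
    mask = np.zeros((nx, ny), dtype=bool)
    for r in range(ny):
        mask[:, ny - 1 - r] = wall_rc[r, :]
    return mask


def load_maze(source, format: str | None = None, *, start: Disc, target: Disc,
              world_extent: tuple[float, float] = (800.0, 800.0),
              initial_wall_mass: float = 1.0) -> MazeGrid:
    """Load a maze from an image file or a '#'/'.' text grid.

    ``format`` is ``'image'`` or ``'text'``; if omitted it is inferred (an
    existing file path ending in an image extension is an image, text blocks
    and ``.txt`` files are text).
    """
    if format is None:
        if isinstance(source, str) and ("\n" in source or set(source) <= {"#", "."}):
            format = "text"
        elif isinstance(source, (str, os.PathLike)) and str(source).lower().endswith(
                (".png", ".pgm", ".tif", ".tiff", ".bmp")):
            format = "image"
        else:
            format = "text"
    if format == "text":
        text = source
        if isinstance(source, (str, os.PathLike)) and os.path.exists(str(source)):
            with open(source) as fh:
                text = fh.read()
        mask = _text_to_mask(text)
    elif format == "image":
        mask = _image_to_mask(str(source))
    else:
        raise ValueError(f"unknown maze format {format!r}")

    nx, ny = mask.shape
    cell_size = world_extent[0] / nx
    grid = MazeGrid(mask.astype(np.float64) * initial_wall_mass, cell_size,
                    world_extent, start, target)
    grid.carve_disc(start)
    grid.carve_disc(target)
    return grid


# ---------------------------------------------------------------------------
# Generation


def _disk_structure(radius_cells: int) -> np.ndarray:
    r = max(1, int(radius_cells))
    y, x = np.ogrid[-r:r + 1, -r:r + 1]
    return x * x + y * y <= r * r


def generate_maze(params: MazeGenParams,
                  world_extent: tuple[float, float] = (800.0, 800.0),
                  start: Disc = Disc((40.0, 40.0), 25.0),
                  target: Disc = Disc((760.0, 760.0), 25.0),
                  cell_size: float = 4.0,
                  initial_wall_mass: float = 1.0) -> MazeGrid:
    """Generate a maze-like labyrinth of thin walls with openings.

    A correlated Gaussian field (correlation length ``pore_scale``) defines
    winding wall bands along its median level-set; the band half-width is
    tuned by bisection so the wall-cell fraction hits ``wall_fraction``.
    A second, independent field (correlation length ``gap_scale``) cuts
    openings over its top ``gap_fraction`` quantile, so every barrier has
    passable gaps somewhere.  A morphological closing at the
    ``wall_thickness`` scale fills pinholes and a final smoothing rounds
    corners.  Deterministic given ``params.seed``.
    """
    nx = int(round(world_extent[0] / cell_size))
    ny = int(round(world_extent[1] / cell_size))
    rng = np.random.default_rng(params.seed)
    noise1 = rng.standard_normal((nx, ny))
    noise2 = rng.standard_normal((nx, ny))
    if params.wall_fraction == 0.0:
        wall = np.zeros((nx, ny), dtype=bool)
    else:
        f1 = ndimage.gaussian_filter(noise1, params.pore_scale / cell_size / 2.0,
                                     mode="reflect")
        f2 = ndimage.gaussian_filter(noise2, params.gap_scale / cell_size / 2.0,
                                     mode="reflect")
        # rank-uniform transform: the median level-set is the 0.5 contour
        r1 = f1.argsort(axis=None).argsort().reshape(f1.shape) / (nx * ny)
        gate = f2 > np.quantile(f2, 1.0 - params.gap_fraction) \
            if params.gap_fraction > 0 else np.zeros_like(r1, dtype=bool)
        lo, hi = 0.0, 0.5
        for _ in range(40):
            mid = 0.5 * (lo + hi)
            frac = np.mean((np.abs(r1 - 0.5) < mid) & ~gate)
            if frac < params.wall_fraction:
                lo = mid
            else:
                hi = mid
        wall = (np.abs(r1 - 0.5) < 0.5 * (lo + hi)) & ~gate
        selem = _disk_structure(round(params.wall_thickness / (2.0 * cell_size)))
        wall = ndimage.binary_closing(wall, structure=selem)
        if params.smoothing > 0:
            wall = ndimage.gaussian_filter(wall.astype(np.float64),
                                           params.smoothing / cell_size) > 0.5

    grid = MazeGrid(wall.astype(np.float64) * initial_wall_mass, cell_size,
                    world_extent, start, target)
    grid.carve_disc(start)
    grid.carve_disc(target)
    if not np.any(grid.wall_mass == 0.0):
        raise ValueError("wall_fraction too high: no open cell after carving")
    return grid


# ---------------------------------------------------------------------------
# Motion and degradation


def wall_normal(maze: MazeGrid, point_on_contact, fallback=None) -> np.ndarray:
    """Outward unit normal of the wall at a contact point.

    Estimated as the negative normalized gradient of the occupancy indicator
    over the 3x3 cell neighborhood of the contact cell; cells outside the
    domain count as wall.  Points from wall into open space.
    """
    cs = maze.cell_size
    ix = int(math.floor(point_on_contact[0] / cs))
    iy = int(math.floor(point_on_contact[1] / cs))
    nx, ny = maze.shape
    gx = gy = 0.0
    seen_wall = False
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            if dx == 0 and dy == 0:
                continue
            jx, jy = ix + dx, iy + dy
            if 0 <= jx < nx and 0 <= jy < ny:
                occ = 1.0 if maze.wall_mass[jx, jy] > 0 else 0.0
            else:
                occ = 1.0
            if occ:
                seen_wall = True
                gx += dx
                gy += dy
    # the contact cell itself may be the only wall around
    if 0 <= ix < nx and 0 <= iy < ny and maze.wall_mass[ix, iy] > 0:
        seen_wall = True
    if not seen_wall and not (0 <= ix < nx and 0 <= iy < ny):
        seen_wall = True
    if not seen_wall:
        raise ValueError("no wall cell within the 3x3 neighborhood")
    norm = math.hypot(gx, gy)
    if norm == 0.0:
        if fallback is None:
            raise ValueError("occupancy gradient vanishes and no fallback given")
        fb = np.asarray(fallback, dtype=np.float64)
        return fb / np.linalg.norm(fb)
    return np.array([-gx / norm, -gy / norm])


def move_with_collision(maze: MazeGrid, pos, vel, dt: float):
    """Advance a point through open space, stopping at the first wall contact.

    The straight segment ``pos -> pos + vel*dt`` is traversed in sub-steps of
    at most ``cell_size/4``; on hitting a wall cell or the domain boundary the
    contact is refined by bisection to within ``cell_size/100`` and the
    outward wall normal at the contact is returned.

    Returns ``(new_pos, normal_or_None)``.  ``pos`` must lie in open space.
    """
    pos = np.asarray(pos, dtype=np.float64)
    vel = np.asarray(vel, dtype=np.float64)
    if maze.blocked(pos):
        raise ValueError("move_with_collision called with pos inside a wall")
    disp = vel * dt
    length = float(np.linalg.norm(disp))
    if length == 0.0:
        return pos.copy(), None
    nsub = max(1, int(math.ceil(length / (maze.cell_size / 4.0))))
    seg = disp / nsub
    seg_len = length / nsub
    p = pos.copy()
    tol = maze.cell_size / 100.0
    for _ in range(nsub):
        cand = p + seg
        if maze.blocked(cand):
            lo, hi = 0.0, 1.0
            while (hi - lo) * seg_len > tol:
                mid = 0.5 * (lo + hi)
                if maze.blocked(p + mid * seg):
                    hi = mid
                else:
                    lo = mid
            contact_pt = p + hi * seg
            normal = wall_normal(maze, contact_pt, fallback=-seg)
            return p + lo * seg, normal
        p = cand
    return p, None


def degrade(maze: MazeGrid, cells, amount_per_cell: float) -> float:
    """Remove up to ``amount_per_cell`` wall mass from each listed cell.

    Mutates the maze in place; a cell becomes open when its mass reaches 0.
    Returns the total mass actually removed.  Wall mass never increases.
    """
    if amount_per_cell < 0:
        raise ValueError("amount_per_cell must be >= 0")
    nx, ny = maze.shape
    removed = 0.0
    for ix, iy in cells:
        if not (0 <= ix < nx and 0 <= iy < ny):
            raise IndexError(f"cell ({ix}, {iy}) outside the raster")
        take = min(maze.wall_mass[ix, iy], amount_per_cell)
        maze.wall_mass[ix, iy] -= take
        removed += take
    return removed
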