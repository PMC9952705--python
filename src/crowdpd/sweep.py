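"""Two-parameter scenario grids: generation, parallel execution, imaging.

Phase behaviour is mapped by sweeping two scenario parameters over an X x Y
grid (columns = axis 1, rows = axis 2), running every cell as an independent
simulation, and tiling the rendered end-state snapshots into one montage
for visual inspection.  The conventional orientation follows the published
phase maps: crowder concentration increases to the right along a row, IDP
concentration increases downward along a column.

Axis parameters are either scalar scenario fields (``epsilon``, ``seed``,
``crowder_repulsion``, ...) or per-species amounts addressed as
``"<species>.fraction"`` / ``"<species>.count"`` (e.g. ``"P48.fraction"``).
"""

from __future__ import annotations

import traceback
from concurrent.futures import ProcessPoolExecutor
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from PIL import Image, ImageDraw

from .analysis import NetworkStats, network_stats
from .builder import (
    SpeciesSpec,
    SystemSpec,
    load_system_spec,
    save_system_spec,
)
from .engine import run as run_scenario
from .io import save_state
from .model import BEAD_TYPES

__all__ = [
    "GridSpec",
    "CellResult",
    "GridResult",
    "generate_scenarios",
    "run_grid",
    "render_snapshot",
    "montage",
    "set_parameter",
]

#: Render colours per bead type (solvent grey, stickers red/orange,
#: backbone blue, crowder yellow).
BEAD_COLORS: dict[str, tuple[int, int, int]] = {
    "W": (200, 200, 200),
    "E": (214, 39, 40),
    "F": (255, 143, 14),
    "B": (60, 100, 200),
    "P": (230, 200, 50),
}

#: Figure-style default visibility: solvent and crowders hidden.
DEFAULT_VISIBILITY: dict[str, bool] = {
    "W": False,
    "E": True,
    "B": True,
    "F": True,
    "P": False,
}


@dataclass(frozen=True)
class GridSpec:
    """An X x Y scenario grid over two parameters of a base scenario."""

    base: SystemSpec
    axis1: tuple[str, tuple[float, ...]]  # columns
    axis2: tuple[str, tuple[float, ...]]  # rows
    visibility: dict[str, bool] = field(default_factory=lambda: dict(DEFAULT_VISIBILITY))

    def __post_init__(self) -> None:
        for name, values in (self.axis1, self.axis2):
            if len(values) == 0:
                raise ValueError(f"axis {name!r} has no values")
            if len(set(values)) != len(values):
                raise ValueError(f"axis {name!r} has duplicate values")

    @property
    def shape(self) -> tuple[int, int]:
        """(X, Y) = (number of columns, number of rows)."""
        return len(self.axis1[1]), len(self.axis2[1])


def set_parameter(spec: SystemSpec, name: str, value: float) -> SystemSpec:
    """Return a scenario with one swept parameter replaced."""
    if "." in name:
        species_name, attr = name.split(".", 1)
        if attr not in ("fraction", "count"):
            raise ValueError(f"unknown species attribute {attr!r}")
        new_species = []
        found = False
        for s in spec.species:
            if s.template.species_name == species_name:
                found = True
                if attr == "fraction":
                    if value > 0:
                        new_species.append(SpeciesSpec(s.template, fraction=float(value)))
                    # a zero fraction removes the species entirely
                else:
                    if value > 0:
                        new_species.append(SpeciesSpec(s.template, count=int(value)))
            else:
                new_species.append(s)
        if not found:
            raise ValueError(f"species {species_name!r} not in the base scenario")
        return replace(spec, species=tuple(new_species))
    if not hasattr(spec, name):
        raise ValueError(f"unknown scenario parameter {name!r}")
    current = getattr(spec, name)
    if isinstance(current, int) and not isinstance(current, bool):
        value = int(value)
    return replace(spec, **{name: value})


def generate_scenarios(grid: GridSpec, outdir: str | Path) -> list[Path]:
    """Write one self-contained scenario file per grid cell.

    The file for column i, row j is named ``i_j_scenario.yaml``.  Each cell
    receives its own seed (base seed + row-major cell index) so parallel
    runs are statistically independent yet exactly reproducible.
    Regeneration from the same GridSpec is byte-identical.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    name1, values1 = grid.axis1
    name2, values2 = grid.axis2
    X, Y = grid.shape
    paths = []
    for j, v2 in enumerate(values2):
        for i, v1 in enumerate(values1):
            spec = set_parameter(grid.base, name1, v1)
            spec = set_parameter(spec, name2, v2)
            spec = replace(spec, seed=grid.base.seed + j * X + i)
            path = outdir / f"{i}_{j}_scenario.yaml"
            save_system_spec(spec, path)
            paths.append(path)
    return paths


@dataclass
class CellResult:
    """Outcome of one grid cell."""

    coords: tuple[int, int]
    scenario: Path
    stats: Optional[NetworkStats] = None
    snapshot: Optional[Path] = None
    error: Optional[str] = None


@dataclass
class GridResult:
    """All cell results of one grid execution."""

    cells: dict[tuple[int, int], CellResult]

    @property
    def n_failed(self) -> int:
        return sum(1 for c in self.cells.values() if c.error is not None)

    def summary_table(self) -> str:
        """Delimited per-cell summary keyed by grid coordinates."""
        lines = [
            "i\tj\tlen_mean\tdense_fraction\tjunction_separation\tjunction_mass\tstatus"
        ]
        for (i, j) in sorted(self.cells):
            c = self.cells[(i, j)]
            if c.error is not None:
                lines.append(f"{i}\t{j}\tnan\tnan\tnan\tnan\tfailed")
            elif c.stats is None:
                lines.append(f"{i}\t{j}\tnan\tnan\tnan\tnan\tno-stats")
            else:
                s = c.stats
                lines.append(
                    f"{i}\t{j}\t{s.len_mean:.3f}\t{s.dense_fraction_mean:.4f}\t"
                    f"{s.junction_separation_mean:.3f}\t{s.junction_mass_mean:.3f}\tok"
                )
        return "\n".join(lines) + "\n"


def _coords_from_name(path: Path) -> tuple[int, int]:
    parts = path.name.split("_")
    return int(parts[0]), int(parts[1])


def _run_one_cell(args) -> tuple[tuple[int, int], Optional[dict], Optional[str], Optional[str]]:
    scenario_path, outdir, cutoff, image_size, visibility = args
    scenario_path = Path(scenario_path)
    coords = _coords_from_name(scenario_path)
    try:
        spec = load_system_spec(scenario_path)
        samples = run_scenario(spec)
        stats = network_stats((s for s in samples), cutoff=cutoff)
        snapshot_path = None
        if outdir is not None:
            outdir = Path(outdir)
            final = samples[-1].state
            prefix = outdir / f"{coords[0]}_{coords[1]}_final"
            save_state(prefix, final)
            img = render_snapshot(final, visibility=visibility, size=image_size)
            snapshot_path = str(prefix.with_suffix(".png"))
            img.save(snapshot_path)
        return coords, stats.as_dict(), snapshot_path, None
    except Exception:
        return coords, None, None, traceback.format_exc()


def run_grid(
    scenarios: Sequence[str | Path],
    max_parallel: int = 1,
    outdir: Optional[str | Path] = None,
    cutoff: float = 1.0,
    image_size: int = 200,
    visibility: Optional[dict[str, bool]] = None,
) -> GridResult:
    """Execute every scenario of a grid, at most ``max_parallel`` at once.

    Cells are fully independent (per-cell seeds, no shared state), so the
    results do not depend on scheduling order.  A failing cell records its
    traceback in its result slot without aborting the rest of the grid.
    """
    if visibility is None:
        visibility = dict(DEFAULT_VISIBILITY)
    if outdir is not None:
        Path(outdir).mkdir(parents=True, exist_ok=True)
    jobs = [
        (str(p), str(outdir) if outdir is not None else None, cutoff, image_size, visibility)
        for p in scenarios
    ]
    if max_parallel <= 1:
        outcomes = [_run_one_cell(job) for job in jobs]
    else:
        with ProcessPoolExecutor(max_workers=max_parallel) as pool:
            outcomes = list(pool.map(_run_one_cell, jobs))
    cells = {}
    for (coords, stats_dict, snapshot, error), path in zip(outcomes, scenarios):
        stats = NetworkStats(**stats_dict) if stats_dict is not None else None
        cells[coords] = CellResult(
            coords=coords,
            scenario=Path(path),
            stats=stats,
            snapshot=Path(snapshot) if snapshot else None,
            error=error,
        )
    return GridResult(cells=cells)


def render_snapshot(
    state,
    visibility: Optional[dict[str, bool]] = None,
    size: int = 200,
    bead_radius: float = 0.4,
    background: tuple[int, int, int] = (255, 255, 255),
) -> Image.Image:
    """Orthographic projection of the box onto the x-y plane.

    Beads are drawn as depth-sorted discs coloured by type; hidden types
    (by default solvent and crowder, matching the published snapshots) are
    omitted.  Rendering is deterministic for a fixed state and settings.
    """
    if visibility is None:
        visibility = dict(DEFAULT_VISIBILITY)
    img = Image.new("RGB", (size, size), background)
    draw = ImageDraw.Draw(img)
    box = np.asarray(state.box, dtype=float)
    scale = size / box[0]
    r_px = max(1.0, bead_radius * scale)
    shown = np.array([visibility.get(BEAD_TYPES[t], True) for t in state.bead_types])
    idx = np.flatnonzero(shown)
    if idx.size:
        order = idx[np.argsort(state.positions[idx, 2], kind="stable")]
        pos = state.positions
        types = state.bead_types
        for i in order:
            x = pos[i, 0] * scale
            y = pos[i, 1] * size / box[1]
            color = BEAD_COLORS[BEAD_TYPES[types[i]]]
            draw.ellipse([x - r_px, y - r_px, x + r_px, y + r_px], fill=color)
    return img


def montage(images: Sequence[Image.Image], X: int, Y: int) -> Image.Image:
    """Tile X*Y equally-sized images row-major into one X-by-Y grid.

    ``images`` is ordered row by row: the first X images form the top row
    (axis-2 value index 0), the next X the second row, and so on; within a
    row, axis-1 values increase to the right.
    """
    if len(images) != X * Y:
        raise ValueError(f"expected {X * Y} images, got {len(images)}")
    sizes = {im.size for im in images}
    if len(sizes) != 1:
        raise ValueError("all tiles must have the same size")
    w, h = images[0].size
    out = Image.new("RGB", (X * w, Y * h))
    for k, im in enumerate(images):
        i, j = k % X, k // X
        out.paste(im, (i * w, j * h))
    return out
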