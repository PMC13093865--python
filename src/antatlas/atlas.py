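"""Mitochondrial genetic-diversity map products.

The colour machinery turns a per-species haplotype distance matrix into map
colours: a classical PCoA (double-centering + eigendecomposition) gives a
two-dimensional configuration, which is min-max scaled onto the unit square
and bilinearly interpolated between four corner colours (blue, yellow, green,
red), so genetically similar haplotypes receive similar colours.  Species
with fewer than three sequences, or with zero maximum intraspecific
distance, are drawn entirely in grey.

Specimens are aggregated into equal-size grid cells over the plotted
bounding box (cell side = longer box side / ``cell_target``); specimens from
labelled islands always form island-exclusive cells.  Every plotted layer is
also emitted as a TSV so downstream checks never parse images.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .distances import DistanceMatrix, SpeciesDistanceSummary
from .haplonet import HaplotypeSet
from .records import SpecimenRecord, ValidationError, round_half_away

__all__ = [
    "CORNER_COLOURS",
    "GREY",
    "ColourAssignment",
    "GridCell",
    "MapCaptionStats",
    "pcoa_2d",
    "unit_square_scale",
    "colour_at",
    "assign_colours",
    "grid_assign",
    "caption_stats",
    "render_maps",
]

# corner -> RGB; (u, v) corners of the unit square
CORNER_COLOURS: dict[tuple[int, int], tuple[int, int, int]] = {
    (0, 0): (0, 0, 255),  # blue, lower-left
    (1, 0): (255, 255, 0),  # yellow, lower-right
    (0, 1): (0, 255, 0),  # green, upper-left
    (1, 1): (255, 0, 0),  # red, upper-right
}
GREY = (128, 128, 128)

_EPS = 1e-12


def pcoa_2d(matrix: DistanceMatrix | np.ndarray, ids: Sequence[str] | None = None) -> np.ndarray:
    """Classical PCoA of a distance matrix, top two positive axes.

    Axis signs are fixed deterministically: on each axis the first id in
    lexicographic order with a non-negligible coordinate is made
    non-negative, so the configuration is invariant to input ordering.
    Degenerate axes (rank < 2) come back as all-zero and scale to 0.5 later.
    """
    if isinstance(matrix, DistanceMatrix):
        ids = matrix.ids
        dist = np.asarray(matrix.values, dtype=float)
    else:
        dist = np.asarray(matrix, dtype=float)
        if ids is None:
            ids = [str(i) for i in range(dist.shape[0])]
    if np.isnan(dist).all():
        raise ValidationError("PCoA needs at least one defined distance")
    dist = np.where(np.isnan(dist), 0.0, dist)
    n = dist.shape[0]
    if n < 2:
        raise ValidationError("PCoA needs at least two haplotypes")

    d2 = dist ** 2
    centering = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * centering @ d2 @ centering
    eigval, eigvec = np.linalg.eigh(b)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]

    coords = np.zeros((n, 2))
    for axis in range(min(2, n)):
        if eigval[axis] > _EPS:
            coords[:, axis] = eigvec[:, axis] * np.sqrt(eigval[axis])

    lex = sorted(range(n), key=lambda i: ids[i])
    for axis in range(2):
        for i in lex:
            if abs(coords[i, axis]) > 1e-9:
                if coords[i, axis] < 0:
                    coords[:, axis] = -coords[:, axis]
                break
    return coords


def unit_square_scale(positions: np.ndarray) -> np.ndarray:
    """Per-axis min-max scaling into [0, 1]; degenerate axes map to 0.5."""
    pos = np.asarray(positions, dtype=float)
    out = np.empty_like(pos)
    for axis in range(pos.shape[1]):
        lo, hi = pos[:, axis].min(), pos[:, axis].max()
        if hi - lo < _EPS:
            out[:, axis] = 0.5
        else:
            out[:, axis] = (pos[:, axis] - lo) / (hi - lo)
    return out


def colour_at(u: float, v: float) -> tuple[int, int, int]:
    """Bilinear corner-colour interpolation at (u, v) in the unit square."""
    if not (0.0 <= u <= 1.0 and 0.0 <= v <= 1.0):
        raise ValidationError(f"({u}, {v}) outside the unit square")
    channels = []
    for c in range(3):
        value = (
            (1 - u) * (1 - v) * CORNER_COLOURS[(0, 0)][c]
            + u * (1 - v) * CORNER_COLOURS[(1, 0)][c]
            + (1 - u) * v * CORNER_COLOURS[(0, 1)][c]
            + u * v * CORNER_COLOURS[(1, 1)][c]
        )
        channels.append(int(round_half_away(value)))
    return tuple(channels)


@dataclass
class ColourAssignment:
    """Haplotype -> unit-square position -> RGB, per species."""

    species: str
    grey_flag: bool
    positions: dict[str, tuple[float, float]] = field(default_factory=dict)
    colours: dict[str, tuple[int, int, int]] = field(default_factory=dict)

    def colour_of(self, hap_id: str) -> tuple[int, int, int]:
        return GREY if self.grey_flag else self.colours[hap_id]


def assign_colours(
    species: str,
    haps: HaplotypeSet,
    matrix: DistanceMatrix | np.ndarray | None,
    n_sequences: int | None = None,
    max_intra: float | None = None,
) -> ColourAssignment:
    """Colour a species' haplotypes; grey when n < 3 or no variation.

    ``matrix`` is the haplotype-level distance matrix (representatives).
    ``max_intra`` defaults to the maximum of that matrix.
    """
    n_seq = haps.total_frequency if n_sequences is None else n_sequences
    hap_ids = [h.hap_id for h in haps.haplotypes]
    if matrix is not None:
        values = (
            matrix.values if isinstance(matrix, DistanceMatrix) else np.asarray(matrix)
        )
        if max_intra is None and values.size:
            defined = values[~np.isnan(values)]
            max_intra = float(defined.max()) if defined.size else None
    if n_seq < 3 or max_intra is None or max_intra == 0.0:
        return ColourAssignment(
            species,
            grey_flag=True,
            positions={},
            colours={h: GREY for h in hap_ids},
        )
    if isinstance(matrix, DistanceMatrix):
        coords = pcoa_2d(matrix)
        ids = matrix.ids
    else:
        coords = pcoa_2d(np.asarray(matrix), hap_ids)
        ids = hap_ids
    scaled = unit_square_scale(coords)
    positions = {ids[i]: (float(scaled[i, 0]), float(scaled[i, 1])) for i in range(len(ids))}
    colours = {hid: colour_at(*positions[hid]) for hid in positions}
    return ColourAssignment(species, False, positions, colours)


# ---------------------------------------------------------------------------
# grid aggregation

@dataclass
class GridCell:
    cell_id: str  # "r<row>c<col>" or "island:<label>"
    member_ids: list[str]
    centroid: tuple[float, float]
    sector_fractions: dict[tuple[int, int, int], float]


def grid_assign(
    records: Sequence[SpecimenRecord],
    colours: Mapping[str, tuple[int, int, int]],
    cell_target: int = 18,
    padding: float = 0.02,
) -> list[GridCell]:
    """Aggregate georeferenced specimens into equal-size cells.

    The bounding box of the plotted coordinates is padded by ``padding`` on
    each side; the cell side is the longer padded side divided by
    ``cell_target``.  Island-labelled records always form their own cells.
    Each cell's pie sectors are the colour frequencies of its members.
    """
    plotted = [
        r
        for r in records
        if r.lat is not None
        and r.lon is not None
        and r.det_status in ("identified", "cf")
    ]
    if not plotted:
        return []

    mainland = [r for r in plotted if r.island is None]
    cells: dict[str, list[SpecimenRecord]] = {}

    lats = [r.lat for r in plotted]
    lons = [r.lon for r in plotted]
    lat_span = max(lats) - min(lats)
    lon_span = max(lons) - min(lons)
    lat0 = min(lats) - padding * max(lat_span, _EPS)
    lon0 = min(lons) - padding * max(lon_span, _EPS)
    side = max(lat_span, lon_span) * (1 + 2 * padding) / cell_target
    if side < _EPS:
        side = 1.0  # all records at one point -> single cell

    for r in mainland:
        row = int((r.lat - lat0) // side)
        col = int((r.lon - lon0) // side)
        cells.setdefault(f"r{row}c{col}", []).append(r)
    for r in plotted:
        if r.island is not None:
            cells.setdefault(f"island:{r.island}", []).append(r)

    out = []
    for cell_id in sorted(cells):
        members = cells[cell_id]
        counts: dict[tuple[int, int, int], int] = {}
        for r in members:
            rgb = colours.get(r.specimen_id, GREY)
            counts[rgb] = counts.get(rgb, 0) + 1
        total = len(members)
        out.append(
            GridCell(
                cell_id=cell_id,
                member_ids=[r.specimen_id for r in members],
                centroid=(
                    sum(r.lat for r in members) / total,
                    sum(r.lon for r in members) / total,
                ),
                sector_fractions={rgb: c / total for rgb, c in counts.items()},
            )
        )
    return out


# ---------------------------------------------------------------------------
# captions and rendering

@dataclass(frozen=True)
class MapCaptionStats:
    species: str
    n_strict: int | None
    max_intra_strict: float | None
    n_loose: int | None
    max_intra_loose: float | None

    def render(self) -> str:
        def fmt(n, v):
            if n is None:
                return "n/a"
            pct = "n/a" if v is None else f"{round_half_away(100 * v, 1)}%"
            return f"n={n}, max p-dist={pct}"

        return (
            f"{self.species} — strict (>2 identified seqs ≥600 bp): "
            f"{fmt(self.n_strict, self.max_intra_strict)}; "
            f"loose (>1 cf-inclusive seq ≥300 bp): "
            f"{fmt(self.n_loose, self.max_intra_loose)}"
        )


def caption_stats(summary: SpeciesDistanceSummary) -> MapCaptionStats:
    """Caption values are the distance module's outputs, verbatim."""
    strict_ok = summary.n_strict > 2 and summary.max_intra is not None
    loose_ok = summary.n_loose > 1 and summary.max_intra_loose is not None
    return MapCaptionStats(
        species=summary.species,
        n_strict=summary.n_strict if strict_ok else None,
        max_intra_strict=summary.max_intra if strict_ok else None,
        n_loose=summary.n_loose if loose_ok else None,
        max_intra_loose=summary.max_intra_loose if loose_ok else None,
    )


def render_maps(
    species: str,
    records: Sequence[SpecimenRecord],
    colours: Mapping[str, tuple[int, int, int]],
    cells: Sequence[GridCell],
    out_dir: str | Path,
    write_images: bool = True,
) -> dict[str, Path]:
    """Write the diversity-map and specimen-map layers (TSV, optional PNG).

    The TSV twins carry every plotted datum: one row per cell sector for the
    diversity map, one row per specimen for the specimen map (source, cf
    status, type flags; faunistic novelties get the diamond marker).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    slug = species.replace(" ", "_")
    outputs: dict[str, Path] = {}

    sector_rows = []
    for cell in cells:
        for rgb, frac in sorted(cell.sector_fractions.items()):
            sector_rows.append(
                {
                    "cell": cell.cell_id,
                    "lat": cell.centroid[0],
                    "lon": cell.centroid[1],
                    "n": len(cell.member_ids),
                    "r": rgb[0],
                    "g": rgb[1],
                    "b": rgb[2],
                    "fraction": frac,
                }
            )
    diversity_tsv = out_dir / f"{slug}_diversity_map.tsv"
    pd.DataFrame(
        sector_rows, columns=["cell", "lat", "lon", "n", "r", "g", "b", "fraction"]
    ).to_csv(diversity_tsv, sep="\t", index=False)
    outputs["diversity_table"] = diversity_tsv

    plotted = [
        r
        for r in records
        if r.lat is not None and r.det_status in ("identified", "cf")
    ]
    specimen_rows = [
        {
            "specimen_id": r.specimen_id,
            "lat": r.lat,
            "lon": r.lon,
            "source": r.source,
            "retrieved": r.source != "de_novo",
            "cf": r.det_status == "cf",
            "type_flags": ";".join(sorted(r.type_flags)),
            "faunistic_novelty": r.faunistic_novelty,
            "marker": "diamond" if r.faunistic_novelty else "circle",
        }
        for r in plotted
    ]
    specimen_tsv = out_dir / f"{slug}_specimen_map.tsv"
    pd.DataFrame(
        specimen_rows,
        columns=[
            "specimen_id",
            "lat",
            "lon",
            "source",
            "retrieved",
            "cf",
            "type_flags",
            "faunistic_novelty",
            "marker",
        ],
    ).to_csv(specimen_tsv, sep="\t", index=False)
    outputs["specimen_table"] = specimen_tsv

    if write_images and plotted:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, axes = plt.subplots(1, 2, figsize=(10, 5))
        for cell in cells:
            start = 0.0
            for rgb, frac in sorted(cell.sector_fractions.items()):
                axes[0].scatter(
                    cell.centroid[1],
                    cell.centroid[0],
                    s=40 + 200 * frac,
                    color=np.array(rgb) / 255.0,
                    alpha=0.8,
                    zorder=2 + start,
                )
                start += frac
        axes[0].set_title(f"{species}: mitochondrial diversity")
        for r in plotted:
            axes[1].scatter(
                r.lon,
                r.lat,
                marker="D" if r.faunistic_novelty else "o",
                c="tab:red" if r.source == "de_novo" else "tab:blue",
                edgecolors="black" if r.det_status == "cf" else "none",
            )
        axes[1].set_title(f"{species}: specimens")
        for ax in axes:
            ax.set_xlabel("longitude")
            ax.set_ylabel("latitude")
        png = out_dir / f"{slug}_maps.png"
        fig.savefig(png, dpi=100)
        plt.close(fig)
        outputs["image"] = png
    return outputs
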