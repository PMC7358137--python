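"""Plate layouts, spot tables and colony-grid image quantification.

The unit record of all array scoring is a *spot table*: one colony area (in
pixels) per grid position of a pinned agar plate.  Layouts attach meaning to
positions — which deletion strain (the *sentinel*) grows there, which query
plasmid (wt gene, a variant, or the empty vector) it carries, and which
adjacent wt-control spot each variant spot is paired with.  Pairing with an
adjacent control is what cancels plate-level colony-size biases: both spots
of a pair share the same local growth conditions, so their difference is
bias-free to first order.

Two standard 1536-spot layouts are provided:

``build_layout_mi1``
    the sentinel-validation design — up to 45 deletion strains pinned as
    4x4 blocks from a 96-well source dish, query rows alternating wt /
    variant, so every variant spot sits directly below its wt control.

``build_layout_mi2``
    the variant-screening design — 8 sentinels in 4-row bands, columns
    alternating wt-control / query, 7 variants plus an empty-vector control
    per plate, 12 replicates of each variant/sentinel combination.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from PIL import Image

from .errors import LayoutError, SchemaError

#: canonical 1536-spot plate geometry (standard SGA density)
ROWS_1536 = 32
COLS_1536 = 48

#: reserved query identifiers
WT_ID = "wt"
VECTOR_ID = "vector"

ROLE_VARIANT = "variant"
ROLE_WT_CONTROL = "wt_control"
ROLE_VECTOR_CONTROL = "vector_control"
ROLE_NEUTRAL_CONTROL = "neutral_control"
ROLE_EMPTY = "empty"

_ROLES = {ROLE_VARIANT, ROLE_WT_CONTROL, ROLE_VECTOR_CONTROL,
          ROLE_NEUTRAL_CONTROL, ROLE_EMPTY}

SPOT_COLUMNS = ["plate_id", "row", "col", "area_px"]


@dataclass(frozen=True)
class Position:
    """Contents of one grid position."""

    strain_id: str
    query_id: str
    role: str

    def __post_init__(self) -> None:
        if self.role not in _ROLES:
            raise LayoutError(f"unknown role {self.role!r}")


@dataclass
class PlateLayout:
    """Grid geometry plus per-position assignments and the pairing map.

    ``pairing`` maps each variant / vector-control position to its adjacent
    wt-control position (Chebyshev distance 1); the orientation of the pair
    is a property of the layout, never assumed by scorers.
    """

    plate_id: str
    rows: int
    cols: int
    positions: dict[tuple[int, int], Position] = field(default_factory=dict)
    pairing: dict[tuple[int, int], tuple[int, int]] = field(default_factory=dict)

    def validate(self) -> None:
        for (r, c) in self.positions:
            if not (0 <= r < self.rows and 0 <= c < self.cols):
                raise LayoutError(f"position {(r, c)} outside {self.rows}x{self.cols} grid")
        paired_targets = set()
        for src, dst in self.pairing.items():
            pos = self.positions.get(src)
            if pos is None or pos.role not in (ROLE_VARIANT, ROLE_VECTOR_CONTROL):
                raise LayoutError(f"pairing source {src} is not a variant/vector position")
            tgt = self.positions.get(dst)
            if tgt is None or tgt.role != ROLE_WT_CONTROL:
                raise LayoutError(f"pairing target {dst} is not a wt_control position")
            if max(abs(src[0] - dst[0]), abs(src[1] - dst[1])) != 1:
                raise LayoutError(f"pair {src}->{dst} not grid-adjacent")
            if dst in paired_targets:
                raise LayoutError(f"pairing not injective: {dst} used twice")
            paired_targets.add(dst)
        for (r, c), pos in self.positions.items():
            if pos.role in (ROLE_VARIANT, ROLE_VECTOR_CONTROL) and (r, c) not in self.pairing:
                raise LayoutError(f"{pos.role} position {(r, c)} has no pairing target")

    def to_frame(self) -> pd.DataFrame:
        """Long-format view: one row per grid position (empty cells included)."""
        rows = []
        for r in range(self.rows):
            for c in range(self.cols):
                pos = self.positions.get((r, c))
                pr, pc = self.pairing.get((r, c), (-1, -1))
                if pos is None:
                    rows.append((self.plate_id, r, c, "", "", ROLE_EMPTY, -1, -1))
                else:
                    rows.append((self.plate_id, r, c, pos.strain_id, pos.query_id,
                                 pos.role, pr, pc))
        return pd.DataFrame(rows, columns=["plate_id", "row", "col", "strain_id",
                                           "query_id", "role", "pair_row", "pair_col"])


@dataclass(frozen=True)
class PlateGeometry:
    """Pixel geometry of a registered plate image.

    ``origin`` is the pixel center of spot (0, 0); spot centers are spaced
    ``pitch`` pixels apart in both directions.
    """

    width: int
    height: int
    origin_x: float
    origin_y: float
    pitch: float
    rows: int
    cols: int

    def __post_init__(self) -> None:
        if self.origin_x + self.pitch * (self.cols - 1) >= self.width:
            raise LayoutError("grid exceeds image width")
        if self.origin_y + self.pitch * (self.rows - 1) >= self.height:
            raise LayoutError("grid exceeds image height")
        if min(self.origin_x, self.origin_y) < 0 or self.pitch <= 0:
            raise LayoutError("origin/pitch out of bounds")

    def center(self, row: int, col: int) -> tuple[float, float]:
        return (self.origin_y + self.pitch * row, self.origin_x + self.pitch * col)


# ---------------------------------------------------------------------------
# layout constructors

def _mi_block_wells() -> list[tuple[int, int]]:
    # 96-well source dish: 8 rows x 12 cols, row-major
    return [(wr, wc) for wr in range(8) for wc in range(12)]


def build_layout_mi1(
    sentinel_ids: Sequence[str],
    neutral_id: str,
    variant_ids: Sequence[str],
    plate_prefix: str = "mi1",
) -> list[PlateLayout]:
    """Sentinel-validation mini-array: one 1536-spot plate per variant query.

    Each deletion strain occupies two source wells (the neutral control
    eight), every well is pinned to a 4x4 block, and plate rows alternate wt
    query (even rows) / variant query (odd rows).  With 44 strains plus the
    neutral control the plate is full: 44*2*16 + 2*64 = 1536 spots, i.e. 16
    replicates per (strain, query) and 64 for the neutral control.  Each
    variant spot is paired with the wt spot one row above.
    """
    sentinel_ids = list(sentinel_ids)
    variant_ids = list(variant_ids)
    if len(sentinel_ids) + 1 > 45:
        raise LayoutError(f"{len(sentinel_ids) + 1} strains exceed the 45-strain mi-1 capacity")
    if len(set(sentinel_ids) | {neutral_id}) != len(sentinel_ids) + 1:
        raise LayoutError("duplicate strain ids")
    if not 1 <= len(variant_ids) <= 5:
        raise LayoutError("mi-1 takes between 1 and 5 variant queries")

    wells = _mi_block_wells()
    well_strains: list[str | None] = []
    for s in sentinel_ids:
        well_strains.extend([s, s])
    well_strains.extend([neutral_id] * 8)
    well_strains.extend([None] * (len(wells) - len(well_strains)))

    layouts = []
    for vid in variant_ids:
        layout = PlateLayout(plate_id=f"{plate_prefix}_{vid}", rows=ROWS_1536, cols=COLS_1536)
        for (wr, wc), strain in zip(wells, well_strains):
            if strain is None:
                continue
            for dr in range(4):
                for dc in range(4):
                    r, c = 4 * wr + dr, 4 * wc + dc
                    if r % 2 == 0:
                        layout.positions[(r, c)] = Position(strain, WT_ID, ROLE_WT_CONTROL)
                    else:
                        role = ROLE_VECTOR_CONTROL if vid == VECTOR_ID else ROLE_VARIANT
                        layout.positions[(r, c)] = Position(strain, vid, role)
                        layout.pairing[(r, c)] = (r - 1, c)
        if len(sentinel_ids) == 44:
            n_spots = len(layout.positions)
            assert n_spots == 44 * 2 * 16 + 2 * 64 == 1536, n_spots
        layout.validate()
        layouts.append(layout)
    return layouts


def build_layout_mi2(
    sentinel_ids: Sequence[str],
    variant_ids: Sequence[str],
    plate_id: str = "mi2",
) -> PlateLayout:
    """Variant-screening mini-array: 8 sentinels x (7 variants + vector).

    Each sentinel occupies a 4-row band; within a band, even columns hold wt
    controls and odd columns hold queries, so every query spot pairs with
    the wt spot immediately to its left.  Queries cycle through the 8 query
    ids, giving 12 replicates per (query, sentinel) and 768 pairs per plate.
    """
    sentinel_ids = list(sentinel_ids)
    variant_ids = list(variant_ids)
    if len(sentinel_ids) != 8:
        raise LayoutError(f"mi-2 requires exactly 8 sentinels, got {len(sentinel_ids)}")
    if len(variant_ids) != 7:
        raise LayoutError(f"mi-2 requires exactly 7 variant queries, got {len(variant_ids)}")
    queries = variant_ids + [VECTOR_ID]

    layout = PlateLayout(plate_id=plate_id, rows=ROWS_1536, cols=COLS_1536)
    for s_idx, strain in enumerate(sentinel_ids):
        q_counter = 0
        for dr in range(4):
            r = 4 * s_idx + dr
            for c in range(0, COLS_1536, 2):
                query = queries[q_counter % len(queries)]
                q_counter += 1
                layout.positions[(r, c)] = Position(strain, WT_ID, ROLE_WT_CONTROL)
                role = ROLE_VECTOR_CONTROL if query == VECTOR_ID else ROLE_VARIANT
                layout.positions[(r, c + 1)] = Position(strain, query, role)
                layout.pairing[(r, c + 1)] = (r, c)
    assert len(layout.pairing) == 768
    layout.validate()
    return layout


# ---------------------------------------------------------------------------
# spot-table I/O

def validate_spot_table(table: pd.DataFrame, source: str = "<table>") -> pd.DataFrame:
    missing = [c for c in SPOT_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"{source}: missing column(s) {missing}")
    area = pd.to_numeric(table["area_px"], errors="coerce")
    bad = table.index[~np.isfinite(area)]
    if len(bad):
        raise SchemaError(f"{source}: non-finite area_px at line(s) {[i + 2 for i in bad[:5]]}")
    neg = table.index[area < 0]
    if len(neg):
        raise SchemaError(f"{source}: negative area_px at line(s) {[i + 2 for i in neg[:5]]}")
    dup = table.duplicated(subset=["plate_id", "row", "col"])
    if dup.any():
        lines = [i + 2 for i in table.index[dup][:5]]
        raise SchemaError(f"{source}: duplicate (plate_id,row,col) at line(s) {lines}")
    out = table.copy()
    out["area_px"] = area.astype(float)
    out["row"] = out["row"].astype(int)
    out["col"] = out["col"].astype(int)
    return out


def read_spot_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    table = pd.read_csv(path, sep="\t", dtype={"plate_id": str})
    return validate_spot_table(table, source=str(path))


def write_spot_table(table: pd.DataFrame, path: str | Path) -> None:
    validate_spot_table(table).to_csv(path, sep="\t", index=False)


def write_layout(layout: PlateLayout, path: str | Path) -> None:
    layout.to_frame().to_csv(path, sep="\t", index=False)


def read_layout(path: str | Path) -> PlateLayout:
    frame = pd.read_csv(path, sep="\t", keep_default_na=False,
                        dtype={"strain_id": str, "query_id": str, "plate_id": str})
    if frame.empty:
        raise SchemaError(f"{path}: empty layout file")
    layout = PlateLayout(plate_id=str(frame["plate_id"].iloc[0]),
                         rows=int(frame["row"].max()) + 1,
                         cols=int(frame["col"].max()) + 1)
    for rec in frame.itertuples(index=False):
        if rec.role == ROLE_EMPTY:
            continue
        layout.positions[(int(rec.row), int(rec.col))] = Position(
            rec.strain_id, rec.query_id, rec.role)
        if int(rec.pair_row) >= 0:
            layout.pairing[(int(rec.row), int(rec.col))] = (int(rec.pair_row), int(rec.pair_col))
    layout.validate()
    return layout


# ---------------------------------------------------------------------------
# plate images

def write_plate_image(image: np.ndarray, path: str | Path) -> None:
    """Save an 8-bit grayscale plate image (PNG/TIFF by extension)."""
    arr = np.asarray(image)
    if arr.dtype != np.uint8 or arr.ndim != 2:
        raise SchemaError("plate images are 2-D uint8 grayscale")
    Image.fromarray(arr, mode="L").save(path)


def read_plate_image(path: str | Path) -> np.ndarray:
    with Image.open(path) as img:
        return np.asarray(img.convert("L"))


def quantify_plate_image(
    image: np.ndarray,
    geometry: PlateGeometry,
    plate_id: str = "plate",
) -> pd.DataFrame:
    """Measure colony areas on a registered grayscale plate image.

    For every grid cell a ``pitch`` x ``pitch`` window is centered on the
    expected spot center; pixels brighter than the midpoint of the window's
    10th and 90th intensity percentiles count toward the area.  The per-cell
    threshold makes the measurement robust to plate-level brightness drift.
    A near-uniform window (90th-10th percentile < 2 intensity units) reports
    area 0.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise SchemaError("expected a 2-D grayscale image")
    if img.shape != (geometry.height, geometry.width):
        raise LayoutError(
            f"image shape {img.shape} does not match geometry "
            f"({geometry.height}, {geometry.width})")
    half = geometry.pitch / 2.0
    records = []
    for r in range(geometry.rows):
        for c in range(geometry.cols):
            cy, cx = geometry.center(r, c)
            y0 = max(int(round(cy - half)), 0)
            y1 = min(int(round(cy + half)), geometry.height)
            x0 = max(int(round(cx - half)), 0)
            x1 = min(int(round(cx + half)), geometry.width)
            window = img[y0:y1, x0:x1]
            p10, p90 = np.percentile(window, [10, 90])
            if p90 - p10 < 2.0:
                area = 0.0
            else:
                area = float(np.count_nonzero(window > (p10 + p90) / 2.0))
            records.append((plate_id, r, c, area))
    return pd.DataFrame(records, columns=SPOT_COLUMNS)


# ---------------------------------------------------------------------------
# paired differences

def pair_differences(table: pd.DataFrame, layout: PlateLayout) -> pd.DataFrame:
    """Area difference of every (variant-or-vector, adjacent wt control) pair.

    ``diff`` is oriented as (variant - paired wt): a query with less activity
    than wt grows better than its control and yields a positive difference.
    The downstream scaling anchors wt-like queries at 0 and the empty-vector
    control at 1.  Records are ordered by (plate, row, col).
    """
    table = validate_spot_table(table)
    sub = table[table["plate_id"] == layout.plate_id]
    areas = {(int(r), int(c)): a for r, c, a in
             zip(sub["row"], sub["col"], sub["area_px"])}
    missing = [pos for pair in layout.pairing.items() for pos in pair if pos not in areas]
    if missing:
        raise SchemaError(
            f"spot table for plate {layout.plate_id!r} missing paired position(s) "
            f"{sorted(set(missing))[:8]}")
    records = []
    for (r, c) in sorted(layout.pairing):
        pr, pc = layout.pairing[(r, c)]
        pos = layout.positions[(r, c)]
        records.append((layout.plate_id, r, c, pos.query_id, pos.strain_id, pos.role,
                        areas[(r, c)], areas[(pr, pc)],
                        areas[(r, c)] - areas[(pr, pc)]))
    return pd.DataFrame(records, columns=[
        "plate_id", "row", "col", "query_id", "strain_id", "role",
        "variant_area", "wt_area", "diff"])
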