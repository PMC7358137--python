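"""Generative models for every input the pipeline consumes.

The generator plants a known truth and emulates the three assay tiers of a
sentinel-interaction-mapping study:

* a genome-scale SDL screen — paired +gene / -gene colony arrays with a
  handful of planted sensitive strains, 3 replicates per screen, 2 screens;
* paired-control mini-arrays — 1536-spot plates where every variant spot is
  adjacent to a wt-control spot, with a multiplicative plate-level size bias
  and multiplicative lognormal spot noise (colony areas are positive and
  plate biases act multiplicatively, which is exactly what adjacent-pair
  differencing is designed to cancel);
* plate-reader growth curves — A600 sampled every 4 min, related to cell
  number through a cubic calibration, with exponential early growth capped
  at a carrying capacity of 50x the inoculum so the standard 6-h fitting
  window stays in log phase.

Each variant carries a true functional level ``f``: 0 = complete loss of
function (indistinguishable from the empty vector), 1 = wt-like, and values
above 1 emulate gain-of-function (constitutively active) alleles.  A spot's
expected area under a sentinel with dynamic range ``d`` is
``base * max(1 - d*f, floor)`` and a culture's true growth rate is
``k0 * (1 - r*f)`` — both linear in activity, so the true loss-of-function
score of a variant is ``1 - f`` in both assays.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import plates
from .errors import ConfigurationError, LayoutError
from .liquid import cubic_is_monotone, evaluate_cubic, invert_cubic
from .plates import PlateLayout, SPOT_COLUMNS, VECTOR_ID, WT_ID

#: expected spot areas never drop below this fraction of base area, so
#: gain-of-function queries (f > 1) still produce measurable colonies
AREA_FLOOR = 0.05

VARIANT_CLASSES = ("lof", "partial", "wtlike", "gof")
GOF_MAX = 1.3


@dataclass(frozen=True)
class VariantTruth:
    """Ground truth for one query allele."""

    variant_id: str
    f: float
    pathogenic: bool
    label_observed: bool


@dataclass(frozen=True)
class SentinelProfile:
    """Growth response of one deletion strain to query activity.

    ``d`` is the array dynamic range: the fraction of colony area lost at
    full (wt) activity.  ``r`` is the liquid analogue for the rate constant,
    whose base value (no gene activity) is ``k0`` per hour.  ``healthy``
    marks strains with no growth defect absent expression.
    """

    strain_id: str
    base_area: float = 200.0
    d: float = 0.5
    k0: float = 0.5
    r: float = 0.5
    healthy: bool = True

    def __post_init__(self) -> None:
        if self.base_area <= 0:
            raise ConfigurationError("base_area must be > 0")
        if not 0 < self.d <= 1:
            raise ConfigurationError("dynamic range d must be in (0, 1]")
        if not 0 < self.r < 1:
            raise ConfigurationError("rate range r must be in (0, 1)")
        if self.k0 * (1 - self.r * GOF_MAX) <= 0:
            raise ConfigurationError("k0*(1 - r*f) must stay positive up to f=1.3")


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the generative model; the seed fully determines outputs."""

    seed: int = 0
    sigma_spot: float = 0.1
    sigma_plate: float = 0.1
    sigma_a600: float = 0.002
    calib_coeffs: tuple[float, float, float, float] = (0.5, 0.2, 1.0, 0.0)
    label_noise: float = 0.1
    n_variants: int = 100
    n_strains: int = 2000
    n_sensitive: int = 20
    replicates: int = 3

    def __post_init__(self) -> None:
        for name in ("sigma_spot", "sigma_plate", "sigma_a600"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if not 0 <= self.label_noise < 0.5:
            raise ConfigurationError("label_noise must be in [0, 0.5)")
        if not cubic_is_monotone(self.calib_coeffs, 0.0, 2.0):
            raise ConfigurationError(
                "calibration polynomial must be strictly increasing on [0, 2]")

    def with_seed(self, seed: int) -> "SimulationConfig":
        return replace(self, seed=seed)


def _mean_one_lognormal(rng: np.random.Generator, sigma: float, size) -> np.ndarray:
    """Multiplicative noise factor with expectation exactly 1 (exactly 1 at sigma=0)."""
    if sigma == 0:
        return np.ones(size)
    return np.exp(rng.normal(0.0, sigma, size) - sigma * sigma / 2.0)


# ---------------------------------------------------------------------------
# variant panel

def generate_variant_panel(
    n: int,
    mix: Mapping[str, float],
    threshold_path: float = 0.5,
    label_noise: float = 0.0,
    seed: int = 0,
) -> list[VariantTruth]:
    """Draw a panel of n variants plus the reserved wt and vector records.

    ``mix`` gives class fractions over {lof, partial, wtlike, gof}: complete
    LoF alleles have f = 0, partial alleles f ~ U(0, 1), wt-like f = 1 and
    gain-of-function alleles f ~ U(1, 1.3].  A variant is pathogenic when
    f <= threshold_path; the observed binary label flips with probability
    ``label_noise`` (reference annotations are imperfect in both directions).
    """
    if n < 1:
        raise ConfigurationError("n must be >= 1")
    unknown = set(mix) - set(VARIANT_CLASSES)
    if unknown:
        raise ConfigurationError(f"mix: unknown class(es) {sorted(unknown)}")
    fracs = np.array([float(mix.get(c, 0.0)) for c in VARIANT_CLASSES])
    if np.any(fracs < 0) or not np.isclose(fracs.sum(), 1.0):
        raise ConfigurationError(f"mix fractions must be >= 0 and sum to 1, got {dict(mix)}")
    if not 0 <= label_noise < 0.5:
        raise ConfigurationError("label_noise must be in [0, 0.5)")

    rng = np.random.default_rng(seed)
    classes = rng.choice(len(VARIANT_CLASSES), size=n, p=fracs)
    panel: list[VariantTruth] = []
    for i, cls in enumerate(classes):
        name = VARIANT_CLASSES[cls]
        if name == "lof":
            f = 0.0
        elif name == "partial":
            f = float(rng.uniform(0.0, 1.0))
        elif name == "wtlike":
            f = 1.0
        else:
            f = float(rng.uniform(1.0, GOF_MAX))
        pathogenic = f <= threshold_path
        flip = bool(rng.random() < label_noise)
        panel.append(VariantTruth(f"v{i:04d}", f, pathogenic,
                                  pathogenic ^ flip))
    panel.append(VariantTruth(WT_ID, 1.0, False, False))
    panel.append(VariantTruth(VECTOR_ID, 0.0, True, True))
    return panel


def panel_frame(panel: Sequence[VariantTruth]) -> pd.DataFrame:
    frame = pd.DataFrame([vars(v) for v in panel])
    if frame["variant_id"].duplicated().any():
        raise ConfigurationError("duplicate variant_id in panel")
    return frame


def panel_lookup(panel: Sequence[VariantTruth]) -> dict[str, float]:
    return {v.variant_id: v.f for v in panel}


# ---------------------------------------------------------------------------
# SDL screen

@dataclass
class SdlScreen:
    """Simulated paired +gene / -gene screen with planted truth.

    ``plus_tables`` / ``minus_tables`` hold one spot table per replicate
    (``screens * replicates_per_screen`` of each); ``strain_map`` assigns
    grid positions (shared across replicates) to strains; ``truth`` lists
    the planted per-strain growth defect delta (0 for insensitive strains).
    """

    strain_map: pd.DataFrame
    plus_tables: list[pd.DataFrame] = field(default_factory=list)
    minus_tables: list[pd.DataFrame] = field(default_factory=list)
    truth: pd.DataFrame | None = None
    replicate_ids: list[tuple[int, int]] = field(default_factory=list)


def simulate_sdl_screen(
    n_strains: int,
    n_sensitive: int,
    defect_range: tuple[float, float] = (0.3, 0.6),
    replicates_per_screen: int = 3,
    screens: int = 2,
    cfg: SimulationConfig = SimulationConfig(),
) -> SdlScreen:
    """Genome-scale screen: sensitive strain i shrinks by a planted delta_i.

    Expected +gene area is ``base_i * (1 - delta_i)`` and -gene area is
    ``base_i``; every plate carries a lognormal plate factor and every spot
    lognormal noise.  Strains are arrayed row-major over as many 32x48
    plates as needed, identically in every replicate.
    """
    if n_sensitive > n_strains:
        raise ConfigurationError(f"n_sensitive ({n_sensitive}) > n_strains ({n_strains})")
    lo, hi = defect_range
    if not (0 < lo <= hi < 1):
        raise ConfigurationError(f"defect_range must satisfy 0 < lo <= hi < 1, got {defect_range}")

    rng = np.random.default_rng(cfg.seed)
    strain_ids = [f"strain{i:04d}" for i in range(n_strains)]
    base = rng.uniform(150.0, 250.0, n_strains)
    delta = np.zeros(n_strains)
    sensitive = rng.choice(n_strains, size=n_sensitive, replace=False)
    delta[sensitive] = rng.uniform(lo, hi, n_sensitive)

    per_plate = plates.ROWS_1536 * plates.COLS_1536
    n_plates = -(-n_strains // per_plate)
    map_records = []
    for i in range(n_strains):
        p, off = divmod(i, per_plate)
        map_records.append((p, off // plates.COLS_1536, off % plates.COLS_1536, strain_ids[i]))
    strain_map = pd.DataFrame(map_records, columns=["plate_ord", "row", "col", "strain_id"])

    screen = SdlScreen(strain_map=strain_map)
    screen.truth = pd.DataFrame({"strain_id": strain_ids, "delta": delta,
                                 "sensitive": delta > 0})
    expected = {"plus": base * (1.0 - delta), "minus": base}
    for s in range(screens):
        for rep in range(replicates_per_screen):
            screen.replicate_ids.append((s, rep))
            for arm in ("plus", "minus"):
                recs = []
                for p in range(n_plates):
                    m_plate = float(_mean_one_lognormal(rng, cfg.sigma_plate, ()))
                    on_plate = strain_map[strain_map["plate_ord"] == p]
                    eps = _mean_one_lognormal(rng, cfg.sigma_spot, len(on_plate))
                    areas = expected[arm][on_plate.index.to_numpy()] * m_plate * eps
                    pid = f"sdl_s{s}r{rep}_{arm}_p{p}"
                    recs.append(pd.DataFrame({
                        "plate_id": pid, "row": on_plate["row"].to_numpy(),
                        "col": on_plate["col"].to_numpy(), "area_px": areas}))
                table = pd.concat(recs, ignore_index=True)
                (screen.plus_tables if arm == "plus" else screen.minus_tables).append(table)
    return screen


# ---------------------------------------------------------------------------
# mini-arrays

def simulate_miniarray(
    layout: PlateLayout,
    panel: Sequence[VariantTruth],
    sentinels: Mapping[str, SentinelProfile],
    cfg: SimulationConfig = SimulationConfig(),
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Spot areas for one mini-array plate under the paired-control model.

    Expected area at a position holding sentinel s under query activity f is
    ``m_plate * base_s * max(1 - d_s * f, AREA_FLOOR)``; the whole plate
    shares one lognormal factor m_plate and every spot gets independent
    lognormal noise.  Empty positions report area 0.  The induced true
    mini-array LoF of a variant is 1 - f.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    f_by_query = panel_lookup(panel)
    f_by_query.setdefault(WT_ID, 1.0)
    f_by_query.setdefault(VECTOR_ID, 0.0)
    m_plate = float(_mean_one_lognormal(rng, cfg.sigma_plate, ()))
    records = []
    for r in range(layout.rows):
        for c in range(layout.cols):
            pos = layout.positions.get((r, c))
            if pos is None:
                records.append((layout.plate_id, r, c, 0.0))
                continue
            prof = sentinels.get(pos.strain_id)
            if prof is None:
                raise LayoutError(f"layout references unknown strain {pos.strain_id!r}")
            if pos.query_id not in f_by_query:
                raise LayoutError(f"layout references unknown query {pos.query_id!r}")
            f = f_by_query[pos.query_id]
            mean_area = m_plate * prof.base_area * max(1.0 - prof.d * f, AREA_FLOOR)
            eps = float(_mean_one_lognormal(rng, cfg.sigma_spot, ()))
            records.append((layout.plate_id, r, c, mean_area * eps))
    return pd.DataFrame(records, columns=SPOT_COLUMNS)


def simulate_miniarray_set(
    layouts: Sequence[PlateLayout],
    panel: Sequence[VariantTruth],
    sentinels: Mapping[str, SentinelProfile],
    cfg: SimulationConfig = SimulationConfig(),
) -> pd.DataFrame:
    """Concatenated spot table for a series of plates (one rng stream)."""
    rng = np.random.default_rng(cfg.seed)
    tables = [simulate_miniarray(lay, panel, sentinels, cfg, rng=rng) for lay in layouts]
    return pd.concat(tables, ignore_index=True)


# ---------------------------------------------------------------------------
# calibration series and growth curves

def simulate_calibration_series(
    true_counts: Sequence[float],
    calib_coeffs: tuple[float, float, float, float],
    sigma: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Serial-dilution readings: A600 obtained by inverting the cubic.

    Returns a table of (a600, relative_cells) with Gaussian read noise on
    the A600 axis; ``relative_cells`` is the exact planted count.
    """
    counts = np.asarray(true_counts, dtype=float)
    a600 = invert_cubic(calib_coeffs, counts)
    if sigma > 0:
        rng = np.random.default_rng(seed)
        a600 = a600 + rng.normal(0.0, sigma, a600.shape)
    return pd.DataFrame({"a600": a600, "relative_cells": counts})


def simulate_growth_curves(
    panel: Sequence[VariantTruth],
    sentinel: SentinelProfile,
    cfg: SimulationConfig = SimulationConfig(),
    wells_per_variant: int = 8,
    duration_h: float = 6.0,
    interval_min: float = 4.0,
    start_a600: float = 0.125,
    capacity_fold: float = 50.0,
) -> pd.DataFrame:
    """A600 time series for every panel entry in one sentinel background.

    Cultures start at A600 0.125; cell number grows as N0*exp(k*t) with
    k = k0*(1 - r*f), saturating at ``capacity_fold`` times the inoculum.
    Readings every ``interval_min`` minutes are produced by inverting the
    calibration cubic and adding Gaussian read noise.
    """
    if interval_min <= 0 or duration_h <= 0:
        raise ConfigurationError("interval and duration must be positive")
    rng = np.random.default_rng(cfg.seed)
    times_min = np.arange(0.0, duration_h * 60.0 + 0.5 * interval_min, interval_min)
    t_h = times_min / 60.0
    y0 = float(evaluate_cubic(cfg.calib_coeffs, start_a600))
    records = []
    for v in panel:
        k = sentinel.k0 * (1.0 - sentinel.r * v.f)
        n_t = np.minimum(y0 * np.exp(k * t_h), capacity_fold * y0)
        a600_true = invert_cubic(cfg.calib_coeffs, n_t)
        for w in range(wells_per_variant):
            noise = rng.normal(0.0, cfg.sigma_a600, a600_true.shape) if cfg.sigma_a600 > 0 \
                else np.zeros_like(a600_true)
            a600 = np.maximum(a600_true + noise, 1e-6)
            well = f"{v.variant_id}_w{w}"
            records.append(pd.DataFrame({
                "well_id": well, "variant_id": v.variant_id,
                "time_min": times_min, "a600": a600}))
    return pd.concat(records, ignore_index=True)


# ---------------------------------------------------------------------------
# plate-image rendering

def render_plate_image(
    spots: pd.DataFrame,
    geometry: plates.PlateGeometry,
    seed: int = 0,
    background_noise: float = 0.0,
    foreground: int = 220,
    background: int = 20,
) -> np.ndarray:
    """Rasterize a spot table as an 8-bit grayscale plate photograph.

    Each spot becomes a filled disk whose pixel count matches its recorded
    area within +-2% (the radius is chosen by search over a fine grid);
    bright colonies on a dark background, optional Gaussian background
    noise.  Spots that would overlap at the given pitch raise an error.
    """
    spots = plates.validate_spot_table(spots)
    img = np.full((geometry.height, geometry.width), float(background))
    max_area = float(spots["area_px"].max()) if len(spots) else 0.0
    if max_area > 0 and 2.0 * np.sqrt(max_area / np.pi) > geometry.pitch - 1:
        raise LayoutError(
            f"largest spot (area {max_area:.0f}px) would overlap at pitch {geometry.pitch}")
    yy, xx = np.mgrid[0:geometry.height, 0:geometry.width]
    for rec in spots.itertuples(index=False):
        area = rec.area_px
        if area < 0.5:
            continue
        cy, cx = geometry.center(int(rec.row), int(rec.col))
        dy, dx, r2 = _disk_for_area(area)
        mask = (yy - (round(cy) + dy)) ** 2 + (xx - (round(cx) + dx)) ** 2 <= r2
        img[mask] = float(foreground)
    if background_noise > 0:
        rng = np.random.default_rng(seed)
        img = img + rng.normal(0.0, background_noise, img.shape)
    return np.clip(np.round(img), 0, 255).astype(np.uint8)


# sub-pixel center offsets tried when rasterizing a disk: an offset shifts
# which lattice points fall inside, filling the gaps between the pixel
# counts reachable with a pixel-centered disk
_DISK_OFFSETS = ((0.0, 0.0), (0.31, 0.0), (0.0, 0.31), (0.31, 0.17),
                 (0.17, 0.31), (0.43, 0.29), (0.29, 0.43), (0.5, 0.25))


def _disk_for_area(area: float) -> tuple[float, float, float]:
    """Center offset and squared radius whose rasterized disk has ~area pixels.

    For each candidate sub-pixel offset the lattice points are ranked by
    squared distance to the center; a squared-radius threshold between the
    k-th and (k+1)-th nearest points encloses exactly k pixels, so the best
    achievable count is found directly rather than by radius search.
    """
    k_target = max(int(round(area)), 1)
    n = int(np.ceil(np.sqrt(area / np.pi))) + 2
    grid = np.mgrid[-n:n + 1, -n:n + 1].reshape(2, -1).T.astype(float)
    best = None
    for dy, dx in _DISK_OFFSETS:
        d2 = np.sort((grid[:, 0] - dy) ** 2 + (grid[:, 1] - dx) ** 2)
        for k in (k_target, k_target - 1, k_target + 1):
            if not 1 <= k < len(d2) or d2[k - 1] == d2[k]:
                continue  # tie: this threshold cannot isolate exactly k points
            err = abs(k - area)
            if best is None or err < best[0]:
                best = (err, dy, dx, (d2[k - 1] + d2[k]) / 2.0)
            if err < 0.5 + 1e-9:
                return best[1], best[2], best[3]
    if best is None:
        raise LayoutError(f"cannot rasterize disk of area {area}")
    return best[1], best[2], best[3]
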