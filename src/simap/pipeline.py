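"""End-to-end orchestration: simulate a study, score it, evaluate recovery.

This module wires the library together the way the assays are run in
practice: a variant panel is screened on mini-array plates (8 sentinels, 12
replicates per variant/sentinel, 7 variants + vector per 1536-spot plate)
and in liquid culture (8 technical replicate wells per variant, readings
every 4 min, exponential fit over the first 6 h).  The analysis drivers,
the command-line interface and the acceptance checks all call these
functions rather than re-implementing any step.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import liquid as lq
from . import miniarray as ma
from . import plates, sdl, synthetic
from .errors import ConfigurationError
from .plates import PlateLayout, VECTOR_ID, WT_ID
from .synthetic import SentinelProfile, SimulationConfig, VariantTruth

DEFAULT_MIX = {"lof": 0.25, "partial": 0.25, "wtlike": 0.25, "gof": 0.25}


def default_sentinel_profiles(
    n: int = 8,
    d_range: tuple[float, float] = (0.1, 0.6),
    base_area: float = 200.0,
    k0: float = 0.5,
    r: float = 0.5,
) -> dict[str, SentinelProfile]:
    """Sentinel panel spanning a spread of array dynamic ranges.

    Dynamic ranges are evenly spaced over ``d_range`` (the real panel spans
    insensitive to highly sensitive strains); all share the same liquid
    response so the liquid assay, which uses a single sentinel, is not
    confounded by the choice.
    """
    ds = np.linspace(d_range[0], d_range[1], n)
    return {f"sent{i:02d}": SentinelProfile(f"sent{i:02d}", base_area=base_area,
                                            d=float(d), k0=k0, r=r)
            for i, d in enumerate(ds)}


def most_sensitive(sentinels: Mapping[str, SentinelProfile]) -> SentinelProfile:
    return max(sentinels.values(), key=lambda p: p.d)


def build_mi2_series(
    variant_ids: Sequence[str],
    sentinel_ids: Sequence[str],
    pad_query: str = WT_ID,
    plate_prefix: str = "mi2",
) -> list[PlateLayout]:
    """Chunk a variant panel into mi-2 plates of 7 variants + vector each.

    A partial final chunk is padded with extra wt-query spots (scored like
    any query but excluded from variant-level outputs as a reserved id), so
    every plate keeps the full 12-replicate pairing structure.
    """
    ids = list(variant_ids)
    layouts = []
    for p, start in enumerate(range(0, len(ids), 7)):
        chunk = ids[start:start + 7]
        chunk += [pad_query] * (7 - len(chunk))
        layouts.append(plates.build_layout_mi2(
            sentinel_ids, chunk, plate_id=f"{plate_prefix}_p{p:02d}"))
    return layouts


# ---------------------------------------------------------------------------
# study simulation

def simulate_study(
    cfg: SimulationConfig,
    mix: Mapping[str, float] = DEFAULT_MIX,
    sentinels: Mapping[str, SentinelProfile] | None = None,
    include_sdl: bool = False,
) -> dict:
    """Generate one complete synthetic study with known truth.

    Returns a dict with the variant panel and truth table, the mi-2 plate
    layouts and their simulated spot table, the calibration dilution series,
    the liquid growth curves (run in the most sensitive sentinel), and —
    optionally — the genome-scale SDL screen.
    """
    if sentinels is None:
        sentinels = default_sentinel_profiles()
    panel = synthetic.generate_variant_panel(
        cfg.n_variants, mix, label_noise=cfg.label_noise, seed=cfg.seed)
    variant_ids = [v.variant_id for v in panel
                   if v.variant_id not in (WT_ID, VECTOR_ID)]
    layouts = build_mi2_series(variant_ids, list(sentinels))
    spot_table = synthetic.simulate_miniarray_set(
        layouts, panel, sentinels, cfg.with_seed(cfg.seed + 1))

    y0 = lq.evaluate_cubic(cfg.calib_coeffs, 0.05)
    y1 = lq.evaluate_cubic(cfg.calib_coeffs, 2.0)
    counts = np.geomspace(max(y0, 1e-3), y1, 24)
    calibration = synthetic.simulate_calibration_series(
        counts, cfg.calib_coeffs, sigma=0.0, seed=cfg.seed + 2)
    curves = synthetic.simulate_growth_curves(
        panel, most_sensitive(sentinels), cfg.with_seed(cfg.seed + 3))

    study = {
        "panel": panel,
        "truth": synthetic.panel_frame(panel),
        "sentinels": dict(sentinels),
        "layouts": layouts,
        "miniarray_spots": spot_table,
        "calibration": calibration,
        "growth_curves": curves,
    }
    if include_sdl:
        study["sdl"] = synthetic.simulate_sdl_screen(
            cfg.n_strains, cfg.n_sensitive, cfg=cfg.with_seed(cfg.seed + 4))
    return study


# ---------------------------------------------------------------------------
# assay runners

def run_miniarray(
    spot_table: pd.DataFrame,
    layouts: Sequence[PlateLayout],
    tol: float = 1.0,
    bh_correct: bool = False,
) -> pd.DataFrame:
    """Paired-difference LoF scores for every (variant, sentinel)."""
    return ma.score_miniarray_set(spot_table, layouts, tol=tol, bh_correct=bh_correct)


def miniarray_variant_scores(scores: pd.DataFrame, sentinel_id: str) -> pd.DataFrame:
    """One sentinel's per-variant scores, reserved queries dropped."""
    sub = scores[(scores["sentinel_id"] == sentinel_id)
                 & ~scores["variant_id"].isin((WT_ID, VECTOR_ID))]
    return sub[["variant_id", "lof", "p_value"]].reset_index(drop=True)


def calibrate_curves(curves: pd.DataFrame, model: lq.CalibrationModel) -> pd.DataFrame:
    """Attach relative cell numbers (column ``y``) to raw A600 curves."""
    out = lq.validate_curves(curves).copy()
    out["y"] = lq.apply_calibration(model, out["a600"].to_numpy())
    return out


def fit_variant_rates(
    calibrated: pd.DataFrame,
    window_h: tuple[float, float] = (0.0, 6.0),
    min_replicates: int = 4,
) -> pd.DataFrame:
    """Headline rate constant per variant from the mean-normalized curve."""
    records = []
    for vid, grp in calibrated.groupby("variant_id", sort=True):
        mean_curve = lq.mean_normalized_curve(grp, min_replicates=min_replicates)
        fit = lq.fit_exponential(mean_curve["time_min"], mean_curve["y"], window_h)
        records.append((vid, fit.a, fit.k, fit.rss, fit.n_points, fit.converged))
    return pd.DataFrame(records, columns=["variant_id", "a", "k", "rss",
                                          "n_points", "converged"])


def fit_well_rates(
    calibrated: pd.DataFrame,
    window_h: tuple[float, float] = (0.0, 6.0),
) -> pd.DataFrame:
    """Per-well rate constants (unaveraged), used for gain-of-function tests."""
    records = []
    for (well, vid), grp in calibrated.groupby(["well_id", "variant_id"], sort=True):
        y = grp.sort_values("time_min")
        fit = lq.fit_exponential(y["time_min"], y["y"] / y["y"].iloc[0], window_h)
        records.append((well, vid, fit.k))
    return pd.DataFrame(records, columns=["well_id", "variant_id", "k"])


def run_liquid(
    curves: pd.DataFrame,
    calibration_table: pd.DataFrame,
    window_h: tuple[float, float] = (0.0, 6.0),
    tol: float = 1e-6,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Full liquid assay: calibrate, fit rates, scale to LoF, test vs wt.

    The LoF score comes from the averaged-curve rate constants; the p-value
    from a two-tailed unpaired t-test of per-well rate constants against the
    wt control wells (which also powers the gain-of-function call).
    """
    model = lq.fit_calibration(calibration_table)
    calibrated = calibrate_curves(curves, model)
    rates = fit_variant_rates(calibrated, window_h)
    by_id = rates.set_index("variant_id")["k"]
    if WT_ID not in by_id.index or VECTOR_ID not in by_id.index:
        raise ConfigurationError("liquid run requires wt and vector control wells")
    k_wt, k_vec = float(by_id[WT_ID]), float(by_id[VECTOR_ID])
    well_rates = fit_well_rates(calibrated, window_h)
    wt_wells = well_rates.loc[well_rates["variant_id"] == WT_ID, "k"].to_numpy()
    records = []
    for vid, k in by_id.items():
        lof = lq.lof_score_liquid(lq.RateTriple(float(k), k_wt, k_vec), tol=tol)
        kv = well_rates.loc[well_rates["variant_id"] == vid, "k"].to_numpy()
        res = lq.gof_test(kv, wt_wells, alpha=alpha) if vid != WT_ID else None
        records.append((vid, float(k), lof,
                        res.p_value if res else 1.0,
                        res.gof if res else False))
    return pd.DataFrame(records, columns=["variant_id", "k", "lof", "p_value", "gof"])


def liquid_variant_scores(liquid_table: pd.DataFrame) -> pd.DataFrame:
    sub = liquid_table[~liquid_table["variant_id"].isin((WT_ID, VECTOR_ID))]
    return sub[["variant_id", "lof", "p_value"]].reset_index(drop=True)


def run_sdl(
    screen: synthetic.SdlScreen,
    alpha: float = 0.05,
    ratio_cutoff: float = 0.8,
) -> dict:
    """Score a simulated SDL screen and classify replicate confidence."""
    scores = sdl.score_strains(screen.plus_tables, screen.minus_tables,
                               screen.strain_map)
    hits = sdl.call_hits(scores, alpha=alpha, ratio_cutoff=ratio_cutoff)
    hit_matrix = sdl.replicate_hit_matrix(screen.plus_tables, screen.minus_tables,
                                          screen.strain_map, ratio_cutoff=ratio_cutoff)
    confidence = sdl.classify_confidence(hit_matrix)
    return {"scores": scores, "hits": hits, "confidence": confidence}


# ---------------------------------------------------------------------------
# dataset I/O (TSV only)

def write_study(study: dict, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    study["truth"].to_csv(outdir / "truth.tsv", sep="\t", index=False)
    plates.write_spot_table(study["miniarray_spots"], outdir / "miniarray_spots.tsv")
    layout_frames = pd.concat([lay.to_frame() for lay in study["layouts"]],
                              ignore_index=True)
    layout_frames.to_csv(outdir / "miniarray_layouts.tsv", sep="\t", index=False)
    study["calibration"].to_csv(outdir / "calibration.tsv", sep="\t", index=False)
    study["growth_curves"].to_csv(outdir / "growth_curves.tsv", sep="\t", index=False)
    if "sdl" in study:
        screen = study["sdl"]
        screen.strain_map.to_csv(outdir / "sdl_strain_map.tsv", sep="\t", index=False)
        screen.truth.to_csv(outdir / "sdl_truth.tsv", sep="\t", index=False)
        for arm, tables in (("plus", screen.plus_tables), ("minus", screen.minus_tables)):
            for i, table in enumerate(tables):
                plates.write_spot_table(table, outdir / f"sdl_{arm}_rep{i}.tsv")


def read_layouts(path: str | Path) -> list[PlateLayout]:
    frame = pd.read_csv(path, sep="\t", keep_default_na=False,
                        dtype={"strain_id": str, "query_id": str, "plate_id": str})
    layouts = []
    for pid, grp in frame.groupby("plate_id", sort=False):
        layout = PlateLayout(plate_id=str(pid),
                             rows=int(grp["row"].max()) + 1,
                             cols=int(grp["col"].max()) + 1)
        for rec in grp.itertuples(index=False):
            if rec.role == plates.ROLE_EMPTY:
                continue
            layout.positions[(int(rec.row), int(rec.col))] = plates.Position(
                rec.strain_id, rec.query_id, rec.role)
            if int(rec.pair_row) >= 0:
                layout.pairing[(int(rec.row), int(rec.col))] = (
                    int(rec.pair_row), int(rec.pair_col))
        layout.validate()
        layouts.append(layout)
    return layouts
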