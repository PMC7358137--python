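"""Mini-array variant scoring: paired differences, LoF scores, sentinel ranks.

Every variant (or empty-vector) spot is scored against its adjacent
wt-control spot; the per-pair difference (variant - wt) cancels plate-level
size bias.  The mini-array loss-of-function score of a variant in a
sentinel background is

    lof = median(variant - paired wt) / median(vector - paired wt)

so wt-like variants score ~0, complete LoF variants ~1 (they behave like
the empty vector), and gain-of-function variants — whose colonies are
*smaller* than the wt controls — score negative.  Significance of each
variant against wt is a two-tailed unpaired Student's t-test on raw colony
pixel areas (variant spots vs the wt-control spots of the same sentinel and
plate); no multiple-testing correction is applied by default, matching the
raw P < 0.05 convention of the assay (a Benjamini-Hochberg option exists).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats import multitest  # optional BH correction

from .errors import ConfigurationError, DegenerateSentinelError, SchemaError
from .plates import PlateLayout, VECTOR_ID, WT_ID, pair_differences


@dataclass(frozen=True)
class PairedComparison:
    """All paired differences for one (variant, sentinel) combination."""

    variant_id: str
    sentinel_id: str
    diffs: tuple[float, ...]
    median_diff: float
    p_value: float

    @property
    def n_pairs(self) -> int:
        return len(self.diffs)


@dataclass(frozen=True)
class LoFScore:
    variant_id: str
    sentinel_id: str
    assay: str
    lof: float
    p_value: float


def compare_to_wt(variant_areas, wt_areas) -> float:
    """Two-tailed unpaired Student's t-test (pooled variance) on raw areas.

    Degenerate conventions: two constant, equal samples give p = 1 (no
    evidence of difference); two constant, unequal samples give p = 0 (the
    difference is certain at zero variance).
    """
    a = np.asarray(variant_areas, dtype=float)
    b = np.asarray(wt_areas, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise SchemaError("need >= 2 observations per sample")
    if np.allclose(a, a[0]) and np.allclose(b, b[0]):
        return 1.0 if np.isclose(a[0], b[0]) else 0.0
    return float(stats.ttest_ind(a, b, equal_var=True).pvalue)


def paired_comparisons(
    table: pd.DataFrame,
    layout: PlateLayout,
) -> list[PairedComparison]:
    """Per (query, sentinel) paired differences and significance on one plate."""
    diffs = pair_differences(table, layout)
    out = []
    for (query, strain), grp in diffs.groupby(["query_id", "strain_id"], sort=True):
        d = tuple(float(x) for x in grp["diff"])
        p = compare_to_wt(grp["variant_area"], grp["wt_area"]) if len(d) >= 2 else np.nan
        out.append(PairedComparison(query, strain, d, float(np.median(d)), p))
    return out


def comparisons_frame(comparisons: Iterable[PairedComparison],
                      plate_id: str | None = None) -> pd.DataFrame:
    frame = pd.DataFrame([{
        "variant_id": c.variant_id, "sentinel_id": c.sentinel_id,
        "n_pairs": c.n_pairs, "median_diff": c.median_diff, "p_value": c.p_value,
    } for c in comparisons])
    if plate_id is not None:
        frame.insert(0, "plate_id", plate_id)
    return frame


def lof_score_miniarray(
    variant_pairs: PairedComparison,
    vector_pairs: PairedComparison,
    tol: float = 1.0,
) -> LoFScore:
    """Scale a variant's median paired difference by the vector control's.

    The denominator is the sentinel's realized dynamic range on this plate;
    below ``tol`` pixels it cannot be distinguished from pairing noise and
    the sentinel is degenerate.
    """
    if abs(vector_pairs.median_diff) < tol:
        raise DegenerateSentinelError(
            f"sentinel {vector_pairs.sentinel_id!r}: |vector median diff| "
            f"{abs(vector_pairs.median_diff):.3g}px < {tol}px")
    return LoFScore(
        variant_id=variant_pairs.variant_id,
        sentinel_id=variant_pairs.sentinel_id,
        assay="miniarray",
        lof=variant_pairs.median_diff / vector_pairs.median_diff,
        p_value=variant_pairs.p_value,
    )


def score_plate(
    table: pd.DataFrame,
    layout: PlateLayout,
    vector_id: str = VECTOR_ID,
    tol: float = 1.0,
) -> pd.DataFrame:
    """LoF scores for every query on one plate, per sentinel.

    The vector control pairs of the *same sentinel and plate* provide the
    denominator, so plate-level bias cancels within each score.  A sentinel
    whose realized dynamic range on this plate is degenerate (vector median
    difference below ``tol`` pixels) cannot be scaled: its comparisons are
    kept (median difference, p-value) but the lof column is NaN, with a
    warning.
    """
    comps = paired_comparisons(table, layout)
    by_key = {(c.variant_id, c.sentinel_id): c for c in comps}
    vectors = {c.sentinel_id: c for c in comps if c.variant_id == vector_id}
    records = []
    for (query, sentinel), comp in sorted(by_key.items()):
        vec = vectors.get(sentinel)
        if vec is None:
            raise SchemaError(f"plate {layout.plate_id!r}: no vector-control pairs "
                              f"for sentinel {sentinel!r}")
        try:
            lof = lof_score_miniarray(comp, vec, tol=tol).lof
        except DegenerateSentinelError as exc:
            warnings.warn(f"plate {layout.plate_id!r}: {exc}; lof undefined",
                          stacklevel=2)
            lof = np.nan
        records.append((layout.plate_id, query, sentinel, comp.n_pairs,
                        comp.median_diff, lof, comp.p_value))
    return pd.DataFrame(records, columns=[
        "plate_id", "variant_id", "sentinel_id", "n_pairs",
        "median_diff", "lof", "p_value"])


def score_miniarray_set(
    tables: pd.DataFrame,
    layouts: Sequence[PlateLayout],
    vector_id: str = VECTOR_ID,
    tol: float = 1.0,
    bh_correct: bool = False,
) -> pd.DataFrame:
    """Score a whole plate series; optionally Benjamini-Hochberg adjust p."""
    frames = [score_plate(tables, lay, vector_id=vector_id, tol=tol) for lay in layouts]
    scores = pd.concat(frames, ignore_index=True)
    if bh_correct:
        ok = scores["p_value"].notna()
        scores.loc[ok, "p_value"] = multitest.multipletests(
            scores.loc[ok, "p_value"], method="fdr_bh")[1]
    return scores


def rank_sentinels(
    comparisons: pd.DataFrame,
    lof_conditions: Sequence[str],
) -> pd.DataFrame:
    """Rank sentinels by mean p-value across the named LoF conditions.

    The conditions are queries expected to abolish function (e.g. two known
    LoF variants and the empty vector); a sensitive sentinel separates all
    of them from wt with small p.  Arithmetic mean of p-values, ascending;
    ties broken by larger mean |median difference|.  Sentinels missing any
    condition are excluded with a warning.
    """
    records = []
    for sentinel, grp in comparisons.groupby("sentinel_id"):
        sub = grp[grp["variant_id"].isin(lof_conditions)]
        present = set(sub["variant_id"])
        if present != set(lof_conditions):
            warnings.warn(f"sentinel {sentinel!r} missing condition(s) "
                          f"{sorted(set(lof_conditions) - present)}; excluded",
                          stacklevel=2)
            continue
        records.append((sentinel, float(sub["p_value"].mean()),
                        float(sub["median_diff"].abs().mean())))
    ranked = pd.DataFrame(records, columns=["sentinel_id", "avg_p", "mean_abs_diff"])
    return ranked.sort_values(["avg_p", "mean_abs_diff"],
                              ascending=[True, False]).reset_index(drop=True)


def significance_calls(
    scores: pd.DataFrame,
    alpha: float = 0.05,
    exclude: Sequence[str] = (WT_ID, VECTOR_ID),
) -> dict[str, set[str]]:
    """Per-sentinel set of variants called different from wt (p < alpha)."""
    calls: dict[str, set[str]] = {}
    for sentinel, grp in scores.groupby("sentinel_id"):
        sub = grp[~grp["variant_id"].isin(exclude)]
        calls[str(sentinel)] = set(sub.loc[sub["p_value"] < alpha, "variant_id"])
    return calls


def set_intersections(sets: Mapping[str, set]) -> pd.DataFrame:
    """Exclusive (UpSet-style) intersections of per-sentinel variant sets.

    Each variant is counted in exactly one combination — the full set of
    sentinels that called it — so combination counts sum to the size of the
    union of the inputs.
    """
    union = set().union(*sets.values()) if sets else set()
    combos: dict[tuple[str, ...], set] = {}
    for item in union:
        combo = tuple(sorted(name for name, members in sets.items() if item in members))
        combos.setdefault(combo, set()).add(item)
    records = [("+".join(combo), len(members), sorted(members))
               for combo, members in sorted(combos.items())]
    return pd.DataFrame(records, columns=["combination", "count", "variant_ids"])
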