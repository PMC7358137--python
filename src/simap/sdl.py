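"""Hit calling for paired +gene / -gene overexpression screens.

A strain is a candidate *sentinel* when overexpressing the query gene gives
it a reproducible growth defect: the mean ratio of normalized colony size
(+gene / -gene) falls below an experimentally defined cutoff and a
two-tailed unpaired Student's t-test across replicates is significant.
Replicate-confidence classes summarize reproducibility across the two
independent screens (3 replicates each): a strain hit in all 6 replicates is
high confidence, in 4-5 of 6 low confidence, otherwise none.  Control
screens (empty vector; catalytically dead variant) filter artifacts.
"""

from __future__ import annotations

import re
import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, SchemaError
from .plates import validate_spot_table

_PLATE_ORD_RE = re.compile(r"_p(\d+)$")


def normalize_plate(table: pd.DataFrame, min_nonzero: int = 10) -> pd.DataFrame:
    """Divide each area by the median of non-zero areas on its plate.

    Zero spots (dead or empty positions) stay zero.  A plate with fewer than
    ``min_nonzero`` growing colonies cannot define a size standard.
    """
    table = validate_spot_table(table)
    out = table.copy()
    for pid, grp in table.groupby("plate_id"):
        nonzero = grp["area_px"][grp["area_px"] > 0]
        if len(nonzero) < min_nonzero:
            raise SchemaError(
                f"plate {pid!r}: only {len(nonzero)} non-zero spots (< {min_nonzero})")
        out.loc[grp.index, "area_px"] = grp["area_px"] / nonzero.median()
    return out


def _replicate_matrix(tables: Sequence[pd.DataFrame], strain_map: pd.DataFrame) -> pd.DataFrame:
    """Strains x replicates matrix of normalized colony sizes."""
    cols = {}
    for i, table in enumerate(tables):
        norm = normalize_plate(table)
        norm = norm.assign(plate_ord=[_plate_ord(p) for p in norm["plate_id"]])
        merged = strain_map.merge(norm, on=["plate_ord", "row", "col"], how="left")
        if merged["area_px"].isna().any():
            missing = merged.loc[merged["area_px"].isna(), "strain_id"].tolist()[:5]
            raise SchemaError(f"replicate {i}: spot table missing strains {missing}")
        cols[i] = merged.set_index("strain_id")["area_px"]
    return pd.DataFrame(cols)


def _plate_ord(plate_id: str) -> int:
    m = _PLATE_ORD_RE.search(str(plate_id))
    if not m:
        raise SchemaError(f"plate_id {plate_id!r} lacks a _p<n> plate-ordinal suffix")
    return int(m.group(1))


def score_strains(
    plus_tables: Sequence[pd.DataFrame],
    minus_tables: Sequence[pd.DataFrame],
    strain_map: pd.DataFrame,
    welch: bool = False,
) -> pd.DataFrame:
    """Per-strain +gene/-gene ratio and t-test p across replicate arrays.

    Ratio = mean(normalized +gene) / mean(normalized -gene); p from the
    two-tailed unpaired Student's t-test (pooled variance by default,
    Welch's behind the flag) comparing the two sets of normalized sizes.
    Strains whose control (-gene) colonies are all dead cannot report and
    are excluded with a warning.
    """
    if len(plus_tables) < 2 or len(minus_tables) < 2:
        raise ConfigurationError("need >= 2 replicates per arm")
    plus = _replicate_matrix(plus_tables, strain_map)
    minus = _replicate_matrix(minus_tables, strain_map)
    if not plus.index.equals(minus.index):
        raise SchemaError("strain sets differ between the two arms")
    mean_plus = plus.mean(axis=1)
    mean_minus = minus.mean(axis=1)
    dead = mean_minus <= 0
    if dead.any():
        warnings.warn(f"{int(dead.sum())} strain(s) with zero -gene mean excluded",
                      stacklevel=2)
    res = stats.ttest_ind(plus.to_numpy(), minus.to_numpy(), axis=1,
                          equal_var=not welch)
    scores = pd.DataFrame({
        "strain_id": plus.index,
        "ratio": np.where(dead, np.nan, mean_plus / mean_minus.where(~dead)),
        "p_value": np.where(np.isnan(res.pvalue), 1.0, res.pvalue),
        "n_replicates": plus.shape[1] + minus.shape[1],
    }).reset_index(drop=True)
    return scores[~dead.to_numpy()].reset_index(drop=True)


def call_hits(scores: pd.DataFrame, alpha: float = 0.05,
              ratio_cutoff: float = 0.8) -> pd.DataFrame:
    """hit <=> p < alpha and ratio < cutoff (growth defect beyond the cutoff)."""
    if not 0 < ratio_cutoff < 1:
        raise ConfigurationError(f"ratio_cutoff must be in (0, 1), got {ratio_cutoff}")
    out = scores.copy()
    out["hit"] = (out["p_value"] < alpha) & (out["ratio"] < ratio_cutoff)
    return out


def replicate_hit_matrix(
    plus_tables: Sequence[pd.DataFrame],
    minus_tables: Sequence[pd.DataFrame],
    strain_map: pd.DataFrame,
    ratio_cutoff: float = 0.8,
) -> pd.DataFrame:
    """Boolean strains x replicates matrix: normalized ratio below cutoff.

    A single colony pair per replicate supports no test statistic, so the
    replicate-level call is purely the ratio criterion.
    """
    plus = _replicate_matrix(plus_tables, strain_map)
    minus = _replicate_matrix(minus_tables, strain_map)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = plus.to_numpy() / minus.to_numpy()
    return pd.DataFrame(ratio < ratio_cutoff, index=plus.index,
                        columns=[f"rep{i}" for i in range(plus.shape[1])])


def classify_confidence(hit_matrix: pd.DataFrame) -> pd.DataFrame:
    """Replicate-confidence classes from per-replicate hit calls.

    Over n = screens x replicates total replicates (n=6 in the standard
    design): hits in all n -> ``high``; in n-2 to n-1 (4-5 of 6) -> ``low``;
    fewer -> ``none``.
    """
    if hit_matrix.isna().any().any():
        bad = hit_matrix.index[hit_matrix.isna().any(axis=1)].tolist()[:5]
        raise SchemaError(f"inconsistent strain sets across replicates: {bad}")
    n = hit_matrix.shape[1]
    h = hit_matrix.sum(axis=1).astype(int)
    cls = np.where(h == n, "high", np.where(h >= n - 2, "low", "none"))
    return pd.DataFrame({"strain_id": hit_matrix.index, "hits": h.to_numpy(),
                         "total": n, "confidence": cls}).reset_index(drop=True)


def filter_control_screens(
    hits: Iterable[str],
    vector_screen_hits: Iterable[str],
    dead_variant_screen_hits: Iterable[str],
) -> pd.DataFrame:
    """Remove artifact hits identified by the two control screens.

    Strains that score in the empty-vector screen respond to the plasmid or
    the overexpression burden itself (``vector-artifact``); strains that
    score with the catalytically dead variant respond to the protein
    independent of its activity (``activity-independent``).  Neither class
    can report on variant function, so both are dropped from the sentinel
    candidate list (annotated, not silently discarded).
    """
    vec = set(vector_screen_hits)
    dead = set(dead_variant_screen_hits)
    records = []
    for strain in hits:
        if strain in vec:
            records.append((strain, "vector-artifact", False))
        elif strain in dead:
            records.append((strain, "activity-independent", False))
        else:
            records.append((strain, "", True))
    return pd.DataFrame(records, columns=["strain_id", "annotation", "retained"])
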