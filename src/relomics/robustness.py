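"""Feature repeatability / reproducibility screening via Lin's CCC.

Features are measured for every lesion under repeated acquisitions and
reconstruction-surrogate conditions; agreement between paired
acquisitions is summarised by the concordance correlation coefficient
and averaged within comparison groups (repeatability, iteration
surrogate, filtering surrogate, all conditions).  Features whose
all-conditions mean CCC exceeds a threshold (default 0.85, strict) form
the robust set carried into outcome modelling.  Volume is excluded from
the screen.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

__all__ = ["ccc", "RobustnessReport", "robustness_screen", "long_format_table"]

DEFAULT_CCC_THRESHOLD = 0.85


def ccc(x, y) -> float:
    """Lin's concordance correlation coefficient with population moments.

    CCC = 2 cov(x, y) / (var(x) + var(y) + (mean(x) - mean(y))^2).

    Degenerate conventions: if both inputs are constant, returns 1 when
    they are equal and 0 otherwise (perfect vs no agreement).
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError("ccc requires paired samples of equal length")
    if x.size < 2:
        raise ValueError("ccc requires >= 2 paired observations")
    mx, my = x.mean(), y.mean()
    vx, vy = x.var(), y.var()
    denom = vx + vy + (mx - my) ** 2
    if denom == 0:
        return 1.0  # identical constants
    cov = ((x - mx) * (y - my)).mean()
    return float(2.0 * cov / denom)


@dataclass
class RobustnessReport:
    """Per-feature mean CCC by comparison group plus robust flags."""

    table: pd.DataFrame            # index=feature; columns: repeatability, iterations, filtering, all_conditions, robust
    threshold: float
    mode: str

    @property
    def robust_features(self) -> list[str]:
        return list(self.table.index[self.table["robust"]])

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index_label="feature")


def long_format_table(wide: pd.DataFrame) -> pd.DataFrame:
    """Melt a wide (lesion_id, repeat_id, condition_id, feature columns...)
    table into the long (..., feature, value) layout."""
    id_cols = ["lesion_id", "repeat_id", "condition_id"]
    return wide.melt(id_vars=id_cols, var_name="feature", value_name="value")


def _condition_axes(condition_ids) -> pd.DataFrame:
    """Split condition labels of the form '<iters>it_<filt>' into axes.

    Conditions carry an iteration surrogate ('it1'/'it2') and a filter
    surrogate ('filt'/'nofilt'); unknown labels fall back to treating
    each condition as its own level on both axes.
    """
    rows = []
    for c in condition_ids:
        parts = str(c).split("_")
        if len(parts) == 2:
            rows.append({"condition_id": c, "iters": parts[0], "filt": parts[1]})
        else:
            rows.append({"condition_id": c, "iters": str(c), "filt": str(c)})
    return pd.DataFrame(rows)


def _group_pairs(acqs: pd.DataFrame) -> dict[str, list[tuple]]:
    """Enumerate admissible acquisition pairs per comparison group.

    ``acqs`` has one row per (repeat_id, condition_id) with the parsed
    iteration / filter axes.  Groups:

    * repeatability: same condition, different repeats;
    * iterations: same repeat and filter level, different iteration level;
    * filtering: same repeat and iteration level, different filter level;
    * all_conditions: every unordered pair of acquisitions.
    """
    # canonical acquisition order so pair orientation (hence pooled CCC)
    # does not depend on input row order
    acqs = acqs.sort_values(["condition_id", "repeat_id"]).reset_index(drop=True)
    keys = [tuple(r) for r in acqs[["repeat_id", "condition_id"]].itertuples(index=False)]
    info = {
        (r.repeat_id, r.condition_id): (r.iters, r.filt)
        for r in acqs.itertuples(index=False)
    }
    groups: dict[str, list[tuple]] = {
        "repeatability": [], "iterations": [], "filtering": [], "all_conditions": [],
    }
    for a, b in combinations(keys, 2):
        (ra, ca), (rb, cb) = a, b
        ia, fa = info[a]
        ib, fb = info[b]
        groups["all_conditions"].append((a, b))
        if ca == cb and ra != rb:
            groups["repeatability"].append((a, b))
        if ra == rb and fa == fb and ia != ib:
            groups["iterations"].append((a, b))
        if ra == rb and ia == ib and fa != fb:
            groups["filtering"].append((a, b))
    return groups


def robustness_screen(
    table: pd.DataFrame,
    threshold: float = DEFAULT_CCC_THRESHOLD,
    mode: str = "pooled",
    exclude: tuple[str, ...] = ("volume",),
) -> RobustnessReport:
    """Screen every feature for robustness across acquisitions.

    Parameters
    ----------
    table : long-format DataFrame with columns
        ``lesion_id, repeat_id, condition_id, feature, value``.
    threshold : robust flag requires all-conditions mean CCC strictly
        above this value.
    mode : 'pooled' computes one CCC per group over all lesion x pair
        observations concatenated; 'paired' computes one CCC per
        acquisition pair (over lesions) and averages.  Pooling
        stabilises tiny-lesion-count CCCs and is the default.
    exclude : feature names dropped from the screen (volume, per the
        45-feature screening convention).
    """
    required = {"lesion_id", "repeat_id", "condition_id", "feature", "value"}
    if not required.issubset(table.columns):
        raise ValueError(f"long-format table must have columns {sorted(required)}")
    if table["lesion_id"].nunique() < 2:
        raise ValueError("robustness screen needs >= 2 lesions")
    if mode not in ("pooled", "paired"):
        raise ValueError("mode must be 'pooled' or 'paired'")

    acqs = (
        table[["repeat_id", "condition_id"]]
        .drop_duplicates()
        .merge(_condition_axes(table["condition_id"].unique()), on="condition_id")
    )
    groups = _group_pairs(acqs)

    # pivot: rows = lesion, columns = (repeat, condition) per feature
    lesions = np.sort(table["lesion_id"].unique())
    features = [f for f in table["feature"].unique() if f not in exclude]
    wide = table.pivot_table(
        index="lesion_id", columns=["repeat_id", "condition_id", "feature"],
        values="value", aggfunc="first",
    ).loc[lesions]

    rows = {}
    for feat in features:
        row = {}
        for gname, pairs in groups.items():
            if not pairs:
                row[gname] = np.nan
                continue
            if mode == "pooled":
                xs, ys = [], []
                for (ra, ca), (rb, cb) in pairs:
                    xs.append(wide[(ra, ca, feat)].to_numpy())
                    ys.append(wide[(rb, cb, feat)].to_numpy())
                row[gname] = ccc(np.concatenate(xs), np.concatenate(ys))
            else:
                vals = [
                    ccc(wide[(ra, ca, feat)].to_numpy(), wide[(rb, cb, feat)].to_numpy())
                    for (ra, ca), (rb, cb) in pairs
                ]
                row[gname] = float(np.mean(vals))
        rows[feat] = row

    report = pd.DataFrame.from_dict(rows, orient="index").loc[features]
    report["robust"] = report["all_conditions"] > threshold
    report.index.name = "feature"
    return RobustnessReport(report, threshold, mode)
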