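"""Study-level aggregation and MDF vs non-MDF comparison.

Per-focus records from many rats are aggregated per colon segment
(ascending/transverse/descending) into incidence, totals, and per-rat
mean ± SD — with rats bearing zero foci counted in the denominator — and
an MDF/ACF index (MDF total as a percent of the non-MDF total per
segment).  Morphometric measures of MDF vs non-MDF are compared on foci
with at least five crypts using Welch's unequal-variance t test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from cryptometry.imgio import SEGMENTS

#: Table 3-style default comparison battery.
DEFAULT_MEASURES = ("ACF_AREA", "ACF_IOD", "ACF_DIAAVG", "ACF_PERIM")

MIN_CRYPTS_DEFAULT = 5


@dataclass
class StudyTable:
    """Flat per-focus table across rats and segments.

    ``df`` needs columns rat_id, segment, focus_id, MDF (bool), and the
    measurement battery; (rat_id, segment, focus_id) must be unique.
    """

    df: pd.DataFrame

    def validate(self) -> None:
        req = {"rat_id", "segment", "focus_id", "MDF"}
        missing = req - set(self.df.columns)
        if missing:
            raise ValueError(f"study table missing columns: {sorted(missing)}")
        bad = set(self.df["segment"].unique()) - set(SEGMENTS)
        if bad:
            raise ValueError(f"unknown segment values: {sorted(bad)}")
        if self.df.duplicated(["rat_id", "segment", "focus_id"]).any():
            raise ValueError("(rat_id, segment, focus_id) must be unique")


@dataclass
class SegmentSummary:
    """Per segment × {non-MDF, MDF}: incidence (%), total count, and
    per-rat mean ± SD (sample SD over all ``n_rats`` rats, zero-bearing
    rats included)."""

    df: pd.DataFrame  # index (segment, cls); cols incidence, total, mean, sd
    n_rats: int

    def cell(self, segment: str, cls: str) -> pd.Series:
        return self.df.loc[(segment, cls)]

    @classmethod
    def from_totals(cls, totals: dict, n_rats: int) -> "SegmentSummary":
        """Build a summary from printed per-segment totals alone
        (incidence and SD unavailable -> NaN); per-rat mean = total/n_rats."""
        rows = []
        for (segment, group), total in totals.items():
            rows.append(
                {
                    "segment": segment,
                    "cls": group,
                    "incidence": np.nan,
                    "total": int(total),
                    "mean": total / n_rats,
                    "sd": np.nan,
                }
            )
        df = pd.DataFrame(rows).set_index(["segment", "cls"])
        return cls(df=df, n_rats=n_rats)


def aggregate_by_segment(table: StudyTable, n_rats: int) -> SegmentSummary:
    """Aggregate a study table into Table 1 shape.

    incidence = 100 × (#rats with ≥1 focus of the class in the segment) /
    n_rats; total = focus count; mean ± SD over all ``n_rats`` rats with
    zeros filled in for rats without foci.
    """
    table.validate()
    df = table.df
    if n_rats < 1:
        raise ValueError("n_rats must be >= 1")
    rat_ids = sorted(df["rat_id"].unique())
    if len(rat_ids) > n_rats:
        raise ValueError(
            f"table contains {len(rat_ids)} distinct rats but n_rats={n_rats}"
        )
    rows = []
    for segment in SEGMENTS:
        seg = df[df["segment"] == segment]
        for cls, sel in (("non_mdf", ~seg["MDF"].astype(bool)), ("mdf", seg["MDF"].astype(bool))):
            sub = seg[sel]
            per_rat = sub.groupby("rat_id").size()
            counts = np.zeros(n_rats)
            counts[: len(per_rat)] = per_rat.to_numpy()
            rows.append(
                {
                    "segment": segment,
                    "cls": cls,
                    "incidence": 100.0 * (per_rat > 0).sum() / n_rats,
                    "total": int(len(sub)),
                    "mean": counts.mean(),
                    "sd": counts.std(ddof=1) if n_rats > 1 else 0.0,
                }
            )
    out = pd.DataFrame(rows).set_index(["segment", "cls"])
    return SegmentSummary(df=out, n_rats=n_rats)


def mdf_index(summary: SegmentSummary) -> tuple[pd.Series, bool]:
    """Per-segment MDF/ACF index: 100 × MDF total / non-MDF total.

    Returns (index by segment, ordering flag).  The flag is true iff the
    index strictly increases ascending → transverse → descending.  A zero
    non-MDF denominator yields NaN (undefined), never an exception.
    """
    vals = {}
    for segment in SEGMENTS:
        try:
            mdf_total = summary.cell(segment, "mdf")["total"]
            non_total = summary.cell(segment, "non_mdf")["total"]
        except KeyError:
            vals[segment] = np.nan
            continue
        vals[segment] = (
            100.0 * mdf_total / non_total if non_total > 0 else np.nan
        )
    idx = pd.Series(vals, name="mdf_acf_index_pct")
    vs = [idx[s] for s in SEGMENTS]
    ordered = bool(
        np.all(np.isfinite(vs)) and vs[0] < vs[1] < vs[2]
    )
    return idx, ordered


def welch_t(a, b) -> tuple[float, float]:
    """Welch's two-sided unequal-variance t test with the degenerate case
    pinned down: two zero-variance groups with equal means give p = 1
    (no evidence of difference), with unequal means p = 0."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.std(ddof=1 if len(a) > 1 else 0) == 0 and b.std(ddof=1 if len(b) > 1 else 0) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return np.inf, 0.0
    t, p = sps.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def compare_mdf(
    table: StudyTable,
    min_crypts: int = MIN_CRYPTS_DEFAULT,
    measures=DEFAULT_MEASURES,
) -> pd.DataFrame:
    """Compare MDF vs non-MDF morphometrics on foci with ≥ ``min_crypts``
    crypts (Table 3 shape).

    Returns one row per measure: group means and SEMs, Welch t statistic
    and two-sided p.  If either group is empty after the crypt-count
    filter, the measure's statistics are NaN (undefined marker).
    """
    table.validate()
    df = table.df
    if "CRYPTCOUNT" not in df.columns:
        raise ValueError("study table lacks a CRYPTCOUNT column")
    sub = df[df["CRYPTCOUNT"] >= min_crypts]
    mdf = sub[sub["MDF"].astype(bool)]
    non = sub[~sub["MDF"].astype(bool)]
    rows = []
    for meas in measures:
        if meas not in sub.columns:
            raise ValueError(f"measure {meas!r} not in study table")
        a = non[meas].dropna().to_numpy()
        b = mdf[meas].dropna().to_numpy()
        row = {
            "measure": meas,
            "n_non_mdf": len(a),
            "n_mdf": len(b),
            "mean_non_mdf": a.mean() if len(a) else np.nan,
            "sem_non_mdf": sps.sem(a) if len(a) > 1 else np.nan,
            "mean_mdf": b.mean() if len(b) else np.nan,
            "sem_mdf": sps.sem(b) if len(b) > 1 else np.nan,
        }
        if len(a) and len(b):
            row["t"], row["p"] = welch_t(a, b)
        else:
            row["t"], row["p"] = np.nan, np.nan
        rows.append(row)
    return pd.DataFrame(rows).set_index("measure")
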