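"""Two-snapshot plot-occupancy surveys: I/O, pairing and event classification.

A survey is a table with one row per 5 x 5 m plot in one survey year.  Plots
carry an along-coast distance to the range limit (``dist_km``, 0 at the limit
and increasing toward the range core), projected planar coordinates in metres,
the area of suitable habitat inside the plot (0--25 m^2), a count of
individuals, and -- for plots that have become unsuitable -- a set of causes
(succession, wind, driftwood, water).

Joining the two snapshots per plot yields the colonisation / extinction event
table the downstream models consume:

* a plot is a *colonisation candidate* if it was unoccupied at the first
  survey and suitable at the second (it need not have been suitable at the
  first);
* a plot is an *extinction candidate* if it was occupied at the first survey,
  regardless of its suitability at the second.

The two pools are disjoint by construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

logger = logging.getLogger(__name__)

#: Recognised causes of a plot becoming unsuitable.
CAUSES = frozenset({"succession", "wind", "driftwood", "water"})

#: Maximum suitable habitat area inside one 5 x 5 m plot.
MAX_PLOT_AREA_M2 = 25.0

REQUIRED_COLUMNS = ("plot_id", "dist_km", "x_m", "y_m", "suitable_area_m2", "abundance")

SURVEY_COLUMNS = REQUIRED_COLUMNS + ("causes", "is_dune", "year")


class SurveyFormatError(ValueError):
    """Structural problem with a survey file (missing column, bad header)."""


class SurveyDataError(ValueError):
    """Row-level problem with survey data (range violation, duplicates)."""


def _parse_causes(token) -> frozenset:
    if token is None or (isinstance(token, float) and np.isnan(token)):
        return frozenset()
    text = str(token).strip()
    if not text:
        return frozenset()
    parts = {p.strip() for p in text.split(";") if p.strip()}
    unknown = parts - CAUSES
    if unknown:
        raise SurveyDataError(f"unknown cause token(s) {sorted(unknown)}")
    return frozenset(parts)


def _format_causes(causes) -> str:
    if not causes:
        return ""
    return ";".join(sorted(causes))


def read_survey(path, year: int | None = None) -> pd.DataFrame:
    """Read one survey snapshot from CSV, validating every row.

    Parameters
    ----------
    path : str or path-like
        CSV with a header row and columns ``plot_id, dist_km, x_m, y_m,
        suitable_area_m2, abundance``; optional ``causes`` (semicolon-
        separated tokens), ``is_dune`` (0/1, default 1) and ``year``.
    year : int, optional
        Survey-year label; overrides any ``year`` column.

    Returns
    -------
    pandas.DataFrame
        One validated row per plot with ``causes`` held as frozensets.

    Raises
    ------
    SurveyFormatError
        If a required column is missing.
    SurveyDataError
        If a row violates a range invariant; the message names the row.
    """
    df = pd.read_csv(path, dtype={"plot_id": str})
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SurveyFormatError(f"{path}: missing required column(s) {missing}")

    for col in ("dist_km", "x_m", "y_m", "suitable_area_m2", "abundance"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        if len(bad):
            raise SurveyDataError(f"{path}: non-numeric {col!r} at row(s) {list(bad[:5])}")
        if coerced.isna().any():
            raise SurveyDataError(
                f"{path}: missing {col!r} at row(s) {list(df.index[coerced.isna()][:5])}"
            )
        df[col] = coerced

    if "year" not in df.columns:
        df["year"] = -1
    if year is not None:
        df["year"] = int(year)
    if "is_dune" not in df.columns:
        df["is_dune"] = True
    else:
        df["is_dune"] = df["is_dune"].fillna(1).astype(int).astype(bool)
    if "causes" in df.columns:
        causes = []
        for i, token in enumerate(df["causes"]):
            try:
                causes.append(_parse_causes(token))
            except SurveyDataError as exc:
                raise SurveyDataError(f"{path}: row {i}: {exc}") from None
        df["causes"] = causes
    else:
        df["causes"] = [frozenset()] * len(df)

    _validate_survey(df, str(path))
    return df.loc[:, list(SURVEY_COLUMNS)]


def _validate_survey(df: pd.DataFrame, label: str) -> None:
    bad = df.index[(df["suitable_area_m2"] < 0) | (df["suitable_area_m2"] > MAX_PLOT_AREA_M2)]
    if len(bad):
        raise SurveyDataError(
            f"{label}: suitable_area_m2 outside [0, {MAX_PLOT_AREA_M2}] at row(s) {list(bad[:5])}"
        )
    bad = df.index[(df["abundance"] < 0) | (df["abundance"] != df["abundance"].round())]
    if len(bad):
        raise SurveyDataError(f"{label}: abundance must be a non-negative integer at row(s) {list(bad[:5])}")
    df["abundance"] = df["abundance"].astype(int)
    bad = df.index[(df["abundance"] > 0) & (~df["is_dune"])]
    if len(bad):
        raise SurveyDataError(f"{label}: occupied plot flagged non-dune at row(s) {list(bad[:5])}")
    has_causes = df["causes"].map(bool)
    bad = df.index[has_causes & (df["suitable_area_m2"] > 0)]
    if len(bad):
        raise SurveyDataError(
            f"{label}: causes recorded for plot with suitable habitat at row(s) {list(bad[:5])}"
        )


def write_survey(df: pd.DataFrame, path) -> None:
    """Write a survey snapshot in the CSV dialect :func:`read_survey` accepts."""
    out = df.copy()
    out["causes"] = out["causes"].map(_format_causes)
    out["is_dune"] = out["is_dune"].astype(int)
    out.to_csv(path, index=False, columns=list(SURVEY_COLUMNS))


def pair_surveys(t1: pd.DataFrame, t2: pd.DataFrame) -> pd.DataFrame:
    """Join the two snapshots per plot and classify candidate pools and events.

    Plots flagged non-dune in either year are excluded (they never held
    coastal dune habitat), as are plots visited in only one year; both
    exclusions are logged.  Coordinates and distance are taken from the
    first survey.

    Returns a table with one row per retained plot: areas, abundances,
    suitability and occupancy at both surveys, the candidate flags, the
    ``colonised`` / ``extinct`` outcomes (pandas NA outside the relevant
    pool) and the second-survey cause set.
    """
    for label, df in (("t1", t1), ("t2", t2)):
        if df["plot_id"].duplicated().any():
            dups = df.loc[df["plot_id"].duplicated(), "plot_id"].tolist()[:5]
            raise SurveyDataError(f"duplicate plot_id in {label}: {dups}")

    a = t1.set_index("plot_id")
    b = t2.set_index("plot_id")
    common = a.index.intersection(b.index)
    n_only = (len(a) - len(common)) + (len(b) - len(common))
    if n_only:
        logger.info("pair_surveys: dropped %d plot(s) present in only one survey", n_only)

    a = a.loc[common]
    b = b.loc[common]
    dune = a["is_dune"].to_numpy() & b["is_dune"].to_numpy()
    if (~dune).any():
        logger.info("pair_surveys: excluded %d non-dune plot(s)", int((~dune).sum()))
    a, b = a.loc[dune], b.loc[dune]

    pairs = pd.DataFrame(
        {
            "plot_id": a.index,
            "dist_km": a["dist_km"].to_numpy(),
            "x_m": a["x_m"].to_numpy(),
            "y_m": a["y_m"].to_numpy(),
            "area_t1": a["suitable_area_m2"].to_numpy(),
            "area_t2": b["suitable_area_m2"].to_numpy(),
            "N_t1": a["abundance"].to_numpy(),
            "N_t2": b["abundance"].to_numpy(),
            "causes_t2": b["causes"].to_numpy(),
        }
    ).reset_index(drop=True)
    pairs["suitable_t1"] = pairs["area_t1"] > 0
    pairs["suitable_t2"] = pairs["area_t2"] > 0
    pairs["occupied_t1"] = pairs["N_t1"] >= 1
    pairs["occupied_t2"] = pairs["N_t2"] >= 1
    pairs["colonisation_candidate"] = ~pairs["occupied_t1"] & pairs["suitable_t2"]
    pairs["extinction_candidate"] = pairs["occupied_t1"]

    colonised = pd.array([pd.NA] * len(pairs), dtype="boolean")
    colonised[pairs["colonisation_candidate"].to_numpy()] = pairs.loc[
        pairs["colonisation_candidate"], "occupied_t2"
    ].to_numpy()
    extinct = pd.array([pd.NA] * len(pairs), dtype="boolean")
    extinct[pairs["extinction_candidate"].to_numpy()] = ~pairs.loc[
        pairs["extinction_candidate"], "occupied_t2"
    ].to_numpy()
    pairs["colonised"] = colonised
    pairs["extinct"] = extinct
    pairs["L_t1"] = np.nan
    return pairs


def local_abundance(pairs: pd.DataFrame, radius_m: float = 500.0) -> pd.DataFrame:
    """Fill ``L_t1``: mean first-survey abundance over all *other* plots within
    ``radius_m`` (planar Euclidean).  Vacant neighbours contribute zero; a plot
    with no neighbour gets NaN.  Exact (KD-tree pair enumeration), not gridded.
    """
    if radius_m <= 0:
        raise ValueError("radius_m must be positive")
    out = pairs.copy()
    xy = out[["x_m", "y_m"]].to_numpy(float)
    n = len(out)
    counts = np.zeros(n, dtype=int)
    sums = np.zeros(n, dtype=float)
    if n > 1:
        pairs_idx = cKDTree(xy).query_pairs(radius_m, output_type="ndarray")
        if len(pairs_idx):
            ii, jj = pairs_idx[:, 0], pairs_idx[:, 1]
            N = out["N_t1"].to_numpy(float)
            np.add.at(counts, ii, 1)
            np.add.at(counts, jj, 1)
            np.add.at(sums, ii, N[jj])
            np.add.at(sums, jj, N[ii])
    with np.errstate(invalid="ignore"):
        L = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    out["L_t1"] = L
    return out


@dataclass(frozen=True)
class EventSummary:
    """Crude event counts, rates and occupancies for a paired survey table."""

    n_candidates_col: int
    n_events_col: int
    crude_c: float  # NaN when the pool is empty
    n_candidates_ext: int
    n_events_ext: int
    crude_e: float
    occupancy_t1: float
    occupancy_t2: float
    occupancy_suitable_t1: float
    occupancy_suitable_t2: float


def _rate(events: int, pool: int) -> float:
    return events / pool if pool else float("nan")


def summarize_events(pairs: pd.DataFrame) -> EventSummary:
    """Crude colonisation / extinction rates and occupancies.

    An empty candidate pool yields a NaN rate, never zero.
    """
    col = pairs["colonisation_candidate"]
    ext = pairs["extinction_candidate"]
    n_col = int(col.sum())
    n_ext = int(ext.sum())
    ev_col = int(pairs.loc[col, "colonised"].fillna(False).sum())
    ev_ext = int(pairs.loc[ext, "extinct"].fillna(False).sum())
    n = len(pairs)
    suit1 = pairs["suitable_t1"]
    suit2 = pairs["suitable_t2"]
    return EventSummary(
        n_candidates_col=n_col,
        n_events_col=ev_col,
        crude_c=_rate(ev_col, n_col),
        n_candidates_ext=n_ext,
        n_events_ext=ev_ext,
        crude_e=_rate(ev_ext, n_ext),
        occupancy_t1=_rate(int(pairs["occupied_t1"].sum()), n),
        occupancy_t2=_rate(int(pairs["occupied_t2"].sum()), n),
        occupancy_suitable_t1=_rate(int((pairs["occupied_t1"] & suit1).sum()), int(suit1.sum())),
        occupancy_suitable_t2=_rate(int((pairs["occupied_t2"] & suit2).sum()), int(suit2.sum())),
    )


def classify_extinction_outcomes(pairs: pd.DataFrame) -> pd.DataFrame:
    """Classify extinct plots as demographic (habitat still suitable) vs
    environmental (habitat lost) extinctions.

    Returns one row per extinct plot with ``still_suitable``, the (possibly
    multi-label) cause set, and ``cause_missing`` flagging unsuitable plots
    with no recorded cause; those rows are excluded from cause proportions.
    """
    ext = pairs.loc[pairs["extinct"].fillna(False).astype(bool)]
    out = pd.DataFrame(
        {
            "plot_id": ext["plot_id"].to_numpy(),
            "dist_km": ext["dist_km"].to_numpy(),
            "still_suitable": ext["suitable_t2"].to_numpy(),
            "causes": ext["causes_t2"].to_numpy(),
        }
    )
    out["cause_missing"] = ~out["still_suitable"] & ~out["causes"].map(bool)
    return out


def extinction_outcome_summary(outcomes: pd.DataFrame) -> dict:
    """Fractions of extinctions that left habitat suitable, and per-cause
    proportions among habitat-loss extinctions (complete-cause subset;
    multi-label, so proportions may sum past one)."""
    complete = outcomes.loc[~outcomes["cause_missing"]]
    n = len(complete)
    n_unsuitable = int((~complete["still_suitable"]).sum())
    causes = complete.loc[~complete["still_suitable"], "causes"]
    props = {
        c: (sum(c in s for s in causes) / n_unsuitable if n_unsuitable else float("nan"))
        for c in sorted(CAUSES)
    }
    return {
        "n_extinct": len(outcomes),
        "n_complete": n,
        "n_unsuitable": n_unsuitable,
        "fraction_still_suitable": (n - n_unsuitable) / n if n else float("nan"),
        "cause_proportions": props,
    }


def write_pairs(pairs: pd.DataFrame, path) -> None:
    """Write the paired-event table as CSV; sets serialised semicolon-separated,
    missing values as empty fields."""
    out = pairs.copy()
    out["causes_t2"] = out["causes_t2"].map(_format_causes)
    out.to_csv(path, index=False, na_rep="")
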