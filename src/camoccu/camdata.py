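"""Camera-trap data preparation.

Turns tagged-video record tables, deployment schedules and site covariates
into the containers the occupancy model consumes: a species x site x
occasion detection array with an effort mask, and standardized design
covariates.

Conventions
-----------
* Occasions are calendar days in the local time of the study, aligned per
  site to that site's first sampling day (occasion 1 = first day).
* Every recorded video is one candidate event; consecutive same-species,
  same-site events closer than ``min_gap_s`` seconds are collapsed onto the
  earlier one. With the usual 60 s camera trigger delay the default
  collapses nothing, so each video counts as an independent event.
* Numeric covariates are standardized to mean 0, sd 1 (n-1 denominator);
  the moments are retained so prediction grids reuse the fit-time scaling.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import date

import numpy as np
import pandas as pd

#: Default vegetation classes; the first level is the treatment reference.
VEG_LEVELS = ("QuercusIlex", "LowMaquis", "HighMaquis", "Conifer", "Other")

#: COVID-19 movement-restriction window used to derive the lockdown factor.
LOCKDOWN_START = date(2020, 3, 9)
LOCKDOWN_END = date(2020, 5, 17)
LOCKDOWN_LEVELS = ("before", "during", "after")

#: Modelled species triple, in natural-parameter order (f1, f2, f3).
DEFAULT_SPECIES = ("marten", "human", "cat")


@dataclass(frozen=True)
class Deployment:
    station_id: str
    start: date
    end: date
    lat: float
    lon: float

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"deployment {self.station_id}: start after end")
        if not (abs(self.lat) <= 90 and abs(self.lon) <= 180):
            raise ValueError(f"deployment {self.station_id}: invalid coordinates")

    @property
    def n_days(self) -> int:
        return (self.end - self.start).days + 1


@dataclass
class DetectionHistory:
    """Species x site x occasion detection indicators with effort mask.

    ``y`` is float with values 0, 1 or NaN (no effort). ``occasion_dates``
    holds, per site, the calendar date of each occasion (NaT where the
    occasion is beyond the deployment).
    """

    species_order: tuple[str, ...]
    site_order: list[str]
    y: np.ndarray                      # (S, n_sites, T)
    occasion_dates: np.ndarray         # (n_sites, T) of datetime64[D] / NaT

    @property
    def mask(self) -> np.ndarray:
        """(n_sites, T) boolean effort mask (True where the camera was active)."""
        return ~np.isnan(self.y[0])

    @property
    def effort(self) -> pd.Series:
        """Active trap days per site."""
        return pd.Series(self.mask.sum(axis=1), index=self.site_order, name="trap_days")

    @property
    def total_trap_days(self) -> int:
        return int(self.mask.sum())

    def to_long(self) -> pd.DataFrame:
        """Long-format table (species, station_id, occasion, date, y); occasion is 1-based."""
        S, n, T = self.y.shape
        rows = []
        for s, sp in enumerate(self.species_order):
            for i, site in enumerate(self.site_order):
                for t in range(T):
                    if np.isnan(self.y[s, i, t]):
                        continue
                    rows.append((sp, site, t + 1,
                                 pd.Timestamp(self.occasion_dates[i, t]).date(),
                                 int(self.y[s, i, t])))
        return pd.DataFrame(rows, columns=["species", "station_id", "occasion", "date", "y"])


@dataclass
class CovariateTable:
    """Site-level and occasion-level model covariates.

    ``site`` is indexed by station_id with columns ``veg`` (categorical),
    ``ele``, ``dist_settl``, ``dist_road``. ``occasion`` maps names to
    (n_sites, T) arrays: ``jdate`` (float, NaN off-effort) and ``lockdown``
    (integer codes into LOCKDOWN_LEVELS, -1 off-effort). ``moments`` stores
    (mean, sd) per standardized numeric variable.
    """

    site: pd.DataFrame
    occasion: dict[str, np.ndarray] = field(default_factory=dict)
    moments: dict[str, tuple[float, float]] = field(default_factory=dict)

    NUMERIC_SITE_COLS = ("ele", "dist_settl", "dist_road")

    def copy(self) -> "CovariateTable":
        return CovariateTable(self.site.copy(),
                              {k: v.copy() for k, v in self.occasion.items()},
                              dict(self.moments))


def extract_events(records: pd.DataFrame, min_gap_s: float = 60.0,
                   known_species: tuple[str, ...] | None = None) -> pd.DataFrame:
    """Distil independent detection events from a tagged-video table.

    Parameters
    ----------
    records : DataFrame with columns ``station_id``, ``species``, ``datetime``.
        A video tagged with several species appears as several rows.
    min_gap_s : events of the same species at the same site closer than this
        many seconds are collapsed to the earlier one.
    known_species : optional whitelist; any other label raises.

    Returns a DataFrame (station_id, species, timestamp) sorted by site then
    time, one row per independent event.
    """
    required = {"station_id", "species", "datetime"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"records table lacks columns: {sorted(missing)}")
    if len(records) == 0:
        return pd.DataFrame(columns=["station_id", "species", "timestamp"])
    ts = pd.to_datetime(records["datetime"], errors="raise", format="ISO8601")
    df = pd.DataFrame({
        "station_id": records["station_id"].astype(str),
        "species": records["species"].astype(str),
        "timestamp": ts,
    })
    if known_species is not None:
        bad = set(df["species"]) - set(known_species)
        if bad:
            raise ValueError(f"unknown species labels: {sorted(bad)}")
    df = df.sort_values(["station_id", "species", "timestamp"], kind="mergesort")
    keep = np.ones(len(df), dtype=bool)
    gap = pd.Timedelta(seconds=min_gap_s)
    grp = df.groupby(["station_id", "species"], sort=False)
    last_kept = np.empty(len(df), dtype="datetime64[ns]")
    idx = 0
    for _, sub in grp:
        prev = None
        for ts_i in sub["timestamp"]:
            if prev is not None and (ts_i - prev) < gap:
                keep[idx] = False
            else:
                prev = ts_i
            idx += 1
    out = df.loc[keep].sort_values(["station_id", "timestamp"], kind="mergesort")
    return out.reset_index(drop=True)


def _deployments_from_frame(deployments: pd.DataFrame) -> list[Deployment]:
    return [
        Deployment(str(r.station_id),
                   pd.Timestamp(r.start_date).date(), pd.Timestamp(r.end_date).date(),
                   float(r.lat), float(r.lon))
        for r in deployments.itertuples()
    ]


def build_detection_history(events: pd.DataFrame, deployments: pd.DataFrame,
                            species_order: tuple[str, ...] = DEFAULT_SPECIES,
                            occasion_length_days: int = 1,
                            max_occasions: int | None = 30) -> DetectionHistory:
    """Bin events into a species x site x occasion detection array.

    Occasion 1 of each site starts on that site's first deployment day;
    occasions past the deployment end, or past ``max_occasions``, are
    missing (NaN). An event outside its site's deployment interval raises —
    it signals a corrupted record table.
    """
    if occasion_length_days < 1:
        raise ValueError("occasion_length_days must be >= 1")
    deps = _deployments_from_frame(deployments)
    site_order = [d.station_id for d in deps]
    site_index = {s: i for i, s in enumerate(site_order)}
    n_occ = [int(np.ceil(d.n_days / occasion_length_days)) for d in deps]
    T = max(n_occ) if max_occasions is None else max_occasions
    S = len(species_order)
    sp_index = {s: k for k, s in enumerate(species_order)}

    y = np.full((S, len(deps), T), np.nan)
    dates = np.full((len(deps), T), np.datetime64("NaT"), dtype="datetime64[D]")
    for i, d in enumerate(deps):
        t_active = min(n_occ[i], T)
        y[:, i, :t_active] = 0.0
        start = np.datetime64(d.start, "D")
        dates[i, :t_active] = start + np.arange(t_active) * occasion_length_days

    ts_col = "timestamp" if "timestamp" in events.columns else "datetime"
    for row in events.itertuples():
        site = str(row.station_id)
        if site not in site_index:
            raise ValueError(f"event at unknown station {site!r}")
        i = site_index[site]
        d = deps[i]
        ev_date = pd.Timestamp(getattr(row, ts_col)).date()
        if not (d.start <= ev_date <= d.end):
            raise ValueError(
                f"event at {site} on {getattr(row, ts_col)} falls outside its "
                f"deployment interval {d.start}..{d.end}")
        sp = str(row.species)
        if sp not in sp_index:
            continue  # species present in records but not modelled
        t = (ev_date - d.start).days // occasion_length_days
        if t < T:
            y[sp_index[sp], i, t] = 1.0
    return DetectionHistory(tuple(species_order), site_order, y, dates)


def make_covariate_table(site_covariates: pd.DataFrame, history: DetectionHistory,
                         veg_levels: tuple[str, ...] = VEG_LEVELS) -> CovariateTable:
    """Assemble the covariate table aligned with a detection history.

    ``site_covariates`` needs columns station_id, veg_type, elevation_m,
    dist_settl_m, dist_road_m. Occasion covariates (Julian date, lockdown
    phase) are derived from the history's occasion dates.
    """
    df = site_covariates.set_index(site_covariates["station_id"].astype(str))
    missing = [s for s in history.site_order if s not in df.index]
    if missing:
        raise ValueError(f"no covariates for stations: {missing}")
    df = df.loc[history.site_order]
    bad_veg = set(df["veg_type"].astype(str)) - set(veg_levels)
    if bad_veg:
        raise ValueError(f"unknown vegetation classes: {sorted(bad_veg)}")
    site = pd.DataFrame({
        "veg": pd.Categorical(df["veg_type"].astype(str), categories=list(veg_levels)),
        "ele": df["elevation_m"].astype(float),
        "dist_settl": df["dist_settl_m"].astype(float),
        "dist_road": df["dist_road_m"].astype(float),
    }, index=df.index)
    if site[["ele", "dist_settl", "dist_road"]].isna().any().any():
        raise ValueError("missing numeric site covariates are not allowed")

    dates = history.occasion_dates
    jdate = np.full(dates.shape, np.nan)
    lock = np.full(dates.shape, -1, dtype=int)
    valid = ~np.isnat(dates)
    doy = np.zeros(dates.shape, dtype=int)
    doy[valid] = ((dates[valid] - dates[valid].astype("datetime64[Y]").astype("datetime64[D]"))
                  .astype(int) + 1)
    jdate[valid] = doy[valid].astype(float)
    d0 = np.datetime64(LOCKDOWN_START, "D")
    d1 = np.datetime64(LOCKDOWN_END, "D")
    lock[valid] = np.where(dates[valid] < d0, 0, np.where(dates[valid] <= d1, 1, 2))
    return CovariateTable(site, {"jdate": jdate, "lockdown": lock})


def standardize_covariates(table: CovariateTable) -> CovariateTable:
    """Scale and center all numeric covariates to mean 0, sd 1 (n-1 sd).

    Julian date is standardized jointly over all active site-occasions.
    Moments are recorded in the returned table; a constant column raises.
    Applying the function to an already-standardized table leaves the
    values unchanged (its moments are 0 and 1).
    """
    out = table.copy()
    moments: dict[str, tuple[float, float]] = {}
    for col in CovariateTable.NUMERIC_SITE_COLS:
        x = out.site[col].to_numpy(dtype=float)
        m, s = float(np.mean(x)), float(np.std(x, ddof=1))
        if s == 0:
            raise ValueError(f"covariate {col!r} has zero variance")
        out.site[col] = (x - m) / s
        moments[col] = (m, s)
    if "jdate" in out.occasion:
        j = out.occasion["jdate"]
        vals = j[~np.isnan(j)]
        m, s = float(np.mean(vals)), float(np.std(vals, ddof=1))
        if s == 0:
            raise ValueError("covariate 'jdate' has zero variance")
        out.occasion["jdate"] = (j - m) / s
        moments["jdate"] = (m, s)
    out.moments = moments
    return out


def apply_moments(site_df: pd.DataFrame, moments: dict[str, tuple[float, float]]) -> pd.DataFrame:
    """Standardize a raw prediction grid with fit-time moments."""
    out = site_df.copy()
    for col, (m, s) in moments.items():
        if col in out.columns:
            out[col] = (out[col].astype(float) - m) / s
    return out


def correlation_screen(table: CovariateTable | pd.DataFrame,
                       threshold: float = 0.60) -> pd.DataFrame:
    """Pearson correlations of all numeric covariate pairs, flagging |r| > threshold."""
    df = table.site if isinstance(table, CovariateTable) else table
    num = df.select_dtypes(include=[float, int])
    if num.shape[1] < 2:
        raise ValueError("need at least two numeric covariates")
    if len(num.dropna()) < 3:
        raise ValueError("need at least three complete rows")
    cols = list(num.columns)
    rows = []
    for a in range(len(cols)):
        for b in range(a + 1, len(cols)):
            r = float(np.corrcoef(num[cols[a]], num[cols[b]])[0, 1])
            rows.append((cols[a], cols[b], r, abs(r) > threshold))
    return pd.DataFrame(rows, columns=["var1", "var2", "r", "flagged"])


# ---------------------------------------------------------------------------
# CSV interfaces

def read_events(path, column_map: dict[str, str] | None = None) -> pd.DataFrame:
    df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns=column_map)
    return df


def read_deployments(path) -> pd.DataFrame:
    return pd.read_csv(path)


def read_site_covariates(path) -> pd.DataFrame:
    return pd.read_csv(path)
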