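"""Read, validate and preprocess camera-station count tables.

A station table has one row per camera station and season, four landscape
covariates (elevation in metres, terrain ruggedness index, proportion of
forest cover, local road density in km/km^2) and per-species occurrence
counts — the total number of records of each species at that station over
the whole session.  Landscape covariates are centred and scaled before
modelling; counts stay on their raw scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SPECIES = (
    "lynx",
    "wolf",
    "fox",
    "wildcat",
    "hare",
    "red_deer",
    "roe_deer",
    "wild_boar",
)

COVARIATES = ("elevation", "tri", "forest", "road_density")

SEASONS = ("winter", "autumn")

REQUIRED_COLUMNS = ("station_id", "season") + COVARIATES + SPECIES


class StationTableError(ValueError):
    """Invalid station-table contents (bad counts, duplicates, ranges)."""


class ConfigurationError(ValueError):
    """Missing or unresolvable input configuration (e.g. absent column)."""


class DegenerateInputError(ValueError):
    """Input that makes the requested computation undefined."""


@dataclass(frozen=True)
class StationTable:
    """Station x season rows of landscape covariates and species counts.

    Parameters
    ----------
    data
        One row per (station_id, season); columns per
        :data:`REQUIRED_COLUMNS`.
    covariate_scaling
        ``{covariate: (mean, sd)}`` recorded when :func:`scale_covariates`
        ran, or ``None`` for a raw-scale table.  The raw values are always
        recoverable as ``scaled * sd + mean``.
    """

    data: pd.DataFrame
    covariate_scaling: dict[str, tuple[float, float]] | None = field(default=None)

    def __post_init__(self) -> None:
        _validate_frame(self.data, scaled=self.covariate_scaling is not None)

    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def is_scaled(self) -> bool:
        return self.covariate_scaling is not None

    def counts(self, species: str) -> np.ndarray:
        return self.data[species].to_numpy(dtype=float)

    def column(self, name: str) -> np.ndarray:
        return self.data[name].to_numpy(dtype=float)

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, StationTable):
            return NotImplemented
        return self.data.equals(other.data) and (
            self.covariate_scaling == other.covariate_scaling
        )


def _validate_frame(df: pd.DataFrame, scaled: bool = False) -> None:
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ConfigurationError(f"missing required column(s): {', '.join(missing)}")
    bad_season = ~df["season"].isin(SEASONS)
    if bad_season.any():
        row = int(np.flatnonzero(bad_season.to_numpy())[0])
        raise StationTableError(
            f"row {row}: season {df['season'].iloc[row]!r} not in {SEASONS}"
        )
    for sp in SPECIES:
        col = df[sp]
        as_float = pd.to_numeric(col, errors="coerce")
        bad = (
            as_float.isna()
            | (as_float < 0)
            | (as_float != np.floor(as_float.fillna(-1)))
        )
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise StationTableError(
                f"row {row}: count {col.iloc[row]!r} for {sp} is not a "
                "non-negative integer"
            )
    dup = df.duplicated(subset=["station_id", "season"])
    if dup.any():
        row = int(np.flatnonzero(dup.to_numpy())[0])
        raise StationTableError(
            f"row {row}: duplicate (station_id, season) = "
            f"({df['station_id'].iloc[row]!r}, {df['season'].iloc[row]!r})"
        )
    if not scaled and ((df["forest"] < 0).any() or (df["forest"] > 1).any()):
        raise StationTableError("forest must lie in [0, 1]")


def read_station_table(path, column_map: dict[str, str] | None = None) -> StationTable:
    """Read a station CSV into a validated, raw-scale :class:`StationTable`.

    Parameters
    ----------
    path
        CSV file with a header row; default column names are
        :data:`REQUIRED_COLUMNS`.
    column_map
        Optional ``{canonical_name: file_column}`` mapping for files whose
        headers differ from the defaults.

    Row order is preserved.  Raises :class:`ConfigurationError` for missing
    columns and :class:`StationTableError` for invalid contents.
    """
    df = pd.read_csv(path)
    if column_map:
        rename = {src: dst for dst, src in column_map.items()}
        missing = [src for src in rename if src not in df.columns]
        if missing:
            raise ConfigurationError(
                f"column_map refers to absent column(s): {', '.join(missing)}"
            )
        df = df.rename(columns=rename)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ConfigurationError(f"missing required column(s): {', '.join(missing)}")
    df = df.loc[:, list(REQUIRED_COLUMNS)].reset_index(drop=True)
    for sp in SPECIES:
        numeric = pd.to_numeric(df[sp], errors="coerce")
        if numeric.notna().all() and (numeric == np.floor(numeric)).all():
            df[sp] = numeric.astype(np.int64)
    table = StationTable(df)
    for season in SEASONS:
        n_season = int((df["season"] == season).sum())
        logger.info("read %d %s rows from %s", n_season, season, path)
    return table


def scale_covariates(table: StationTable) -> StationTable:
    """Centre and scale each landscape covariate to mean 0, sample sd 1.

    Counts are untouched.  The (mean, sd) pairs are stored on the returned
    table so raw values are recoverable.  Scaling an already-scaled table is
    idempotent up to floating point.  A constant covariate column raises
    :class:`DegenerateInputError`.
    """
    df = table.data.copy()
    scaling: dict[str, tuple[float, float]] = {}
    for cov in COVARIATES:
        x = df[cov].to_numpy(dtype=float)
        mean = float(np.mean(x))
        sd = float(np.std(x, ddof=1))
        if sd == 0.0 or not np.isfinite(sd):
            raise DegenerateInputError(f"covariate {cov!r} is constant; cannot scale")
        df[cov] = (x - mean) / sd
        if table.covariate_scaling is not None and cov in table.covariate_scaling:
            prev_mean, prev_sd = table.covariate_scaling[cov]
            # compose so raw values stay recoverable after re-scaling
            scaling[cov] = (prev_mean + mean * prev_sd, sd * prev_sd)
        else:
            scaling[cov] = (mean, sd)
    return StationTable(df, covariate_scaling=scaling)


def pearson_correlations(table: StationTable, warn_threshold: float = 0.25) -> pd.DataFrame:
    """Pairwise Pearson correlations between the landscape covariates.

    Returns a symmetric matrix with unit diagonal, indexed by covariate
    name.  Any off-diagonal ``|r| >= warn_threshold`` is logged as a
    warning: the modelling assumes approximately independent covariates.
    """
    if table.n < 3:
        raise DegenerateInputError("need at least 3 rows for correlations")
    sub = table.data.loc[:, list(COVARIATES)].astype(float)
    corr = sub.corr(method="pearson")
    for i, a in enumerate(COVARIATES):
        for b in COVARIATES[i + 1 :]:
            r = corr.loc[a, b]
            if abs(r) >= warn_threshold:
                logger.warning(
                    "covariates %s and %s correlate at r=%.3f (>= %.2f)",
                    a,
                    b,
                    r,
                    warn_threshold,
                )
    return corr


def detection_summary(table: StationTable) -> pd.DataFrame:
    """Per-species detection totals, percentages and per-season shares.

    Returns a frame indexed by species with columns ``total``, ``percent``
    (share of the grand total; NaN when no detections at all), and one
    ``share_<season>`` column per season.  Totals sum to the grand total
    and are invariant to row order.
    """
    if table.n == 0:
        raise DegenerateInputError("empty table")
    totals = table.data.loc[:, list(SPECIES)].sum(axis=0).astype(float)
    grand = float(totals.sum())
    out = pd.DataFrame({"total": totals})
    out["percent"] = totals / grand * 100.0 if grand > 0 else np.nan
    for season in SEASONS:
        mask = table.data["season"] == season
        season_tot = table.data.loc[mask, list(SPECIES)].sum(axis=0).astype(float)
        out[f"share_{season}"] = np.where(totals > 0, season_tot / totals, np.nan)
    out.attrs["grand_total"] = grand
    return out
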