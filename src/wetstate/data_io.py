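"""Reading, validation and export of detection histories and covariate tables.

The package works on long-format ("tidy") inputs:

* ``histories.csv`` — columns ``site_id, year, survey, code`` where ``code`` is
  0 (observed dry), 1 (observed wet, no breeding evidence), 2 (breeding
  evidence).  An absent row is a missing survey.
* ``site_covariates.csv`` — ``site_id, depth_class, veg_ave`` with
  ``depth_class`` the ordinal maximum-depth class 1–4 (<0.5, 0.5–1, 1–2, >2 m)
  and ``veg_ave`` the decade-average emergent-vegetation cover in percent.
* ``site_year_covariates.csv`` — ``site_id, year, veg, precip, evap, runoff``
  (optionally ``*_lag1`` columns), with ``precip``/``evap`` the April–June sums
  in mm and ``runoff`` the annual sum in mm.

Internally observations live in a dense ``(n_sites, n_years, n_surveys)``
integer array with :data:`MISSING` (−1) marking unsurveyed slots, and each
covariate in an ``(n_sites, n_years)`` float array (site-static covariates are
broadcast across years).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = -1
VALID_CODES = (0, 1, 2)

#: annual site-year covariates as stored on StudyData
ANNUAL_COVARIATES = ("veg", "precip", "evap", "RO")
#: map from model-grammar token to the underlying annual covariate it averages
AVERAGE_OF = {"Vegave": "veg", "Precipave": "precip", "Evapave": "evap", "ROave": "RO"}


class DataError(ValueError):
    """Malformed input file or unresolvable covariate."""


@dataclass
class ValidationReport:
    errors: list = field(default_factory=list)     # (site_id, year, message)
    warnings: list = field(default_factory=list)   # (site_id, year, message)
    n_sites_retained: int = 0
    n_sites_dropped: int = 0
    excluded_sites: list = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors


@dataclass
class StudyData:
    """Detection histories joined to site-static and site-year covariates."""

    site_ids: np.ndarray          # (n_sites,) str
    years: np.ndarray             # (T,) consecutive calendar years
    obs: np.ndarray               # (n_sites, T, S) int, MISSING = -1
    depth_class: np.ndarray       # (n_sites,) float in {1,2,3,4}
    veg_ave: np.ndarray           # (n_sites,) percent cover
    site_year: dict               # name -> (n_sites, T) float array (NaN ok)

    @property
    def n_sites(self) -> int:
        return len(self.site_ids)

    @property
    def n_years(self) -> int:
        return len(self.years)

    @property
    def n_surveys(self) -> int:
        return self.obs.shape[2]

    @property
    def n_site_visits(self) -> int:
        """Number of site-years with at least one completed survey."""
        return int(((self.obs != MISSING).any(axis=2)).sum())

    def covariate(self, name: str):
        """Resolve a model-grammar covariate token to an (n_sites, T) array.

        Tokens: annual values ``veg, precip, evap, RO`` and their ``_lag1``
        copies; site-static ``depth`` / ``Depthave`` (the ordinal depth class)
        and ``Vegave``; decade averages ``Precipave, Evapave, ROave`` (per-site
        means over years of the annual value).  Product terms ``a*b`` are
        resolved at design-matrix construction, not here.
        """
        T = self.n_years
        if name in self.site_year:
            return self.site_year[name]
        if name in ("depth", "Depthave"):
            return np.broadcast_to(self.depth_class[:, None], (self.n_sites, T))
        if name == "Vegave":
            return np.broadcast_to(self.veg_ave[:, None], (self.n_sites, T))
        if name in AVERAGE_OF:
            base = self.site_year[AVERAGE_OF[name]]
            with np.errstate(invalid="ignore"):
                ave = np.nanmean(base, axis=1)
            return np.broadcast_to(ave[:, None], (self.n_sites, T))
        if name.endswith("_lag1"):
            base = self.covariate(name[:-5])
            lagged = np.full_like(np.asarray(base, dtype=float), np.nan)
            lagged[:, 1:] = base[:, :-1]
            return lagged
        raise DataError(f"unknown covariate {name!r}")

    def has_covariate(self, name: str) -> bool:
        try:
            self.covariate(name)
            return True
        except DataError:
            return False

    def subset(self, keep: np.ndarray) -> "StudyData":
        """Return a copy restricted to the boolean/integer site index ``keep``."""
        return StudyData(
            site_ids=self.site_ids[keep],
            years=self.years.copy(),
            obs=self.obs[keep],
            depth_class=self.depth_class[keep],
            veg_ave=self.veg_ave[keep],
            site_year={k: v[keep] for k, v in self.site_year.items()},
        )


def read_study_data(history_path, site_covar_path, site_year_covar_path,
                    n_surveys: int = 2) -> StudyData:
    """Read the three delimited tables into a :class:`StudyData`.

    Years are re-indexed onto the consecutive range spanned by the data; any
    site-year-survey without a row is marked MISSING.
    """
    hist = pd.read_csv(history_path)
    required = {"site_id", "year", "survey", "code"}
    if not required.issubset(hist.columns):
        raise DataError(f"{history_path}: expected columns {sorted(required)}")
    bad = ~hist["code"].isin(VALID_CODES)
    if bad.any():
        row = hist.index[bad][0]
        raise DataError(
            f"{history_path}: line {row + 2}: unknown observation code "
            f"{hist.loc[row, 'code']!r} (expected 0, 1 or 2)"
        )
    if hist["survey"].min() < 1 or hist["survey"].max() > n_surveys:
        raise DataError(f"{history_path}: survey index outside 1..{n_surveys}")

    site_cov = pd.read_csv(site_covar_path)
    if not {"site_id", "depth_class", "veg_ave"}.issubset(site_cov.columns):
        raise DataError(f"{site_covar_path}: expected site_id, depth_class, veg_ave")
    sy_cov = pd.read_csv(site_year_covar_path)
    if not {"site_id", "year"}.issubset(sy_cov.columns):
        raise DataError(f"{site_year_covar_path}: expected site_id, year columns")

    site_ids = np.array(sorted(set(hist["site_id"].astype(str))
                               | set(site_cov["site_id"].astype(str))))
    y0, y1 = int(hist["year"].min()), int(hist["year"].max())
    y0 = min(y0, int(sy_cov["year"].min()))
    y1 = max(y1, int(sy_cov["year"].max()))
    years = np.arange(y0, y1 + 1)
    site_index = {s: i for i, s in enumerate(site_ids)}

    obs = np.full((len(site_ids), len(years), n_surveys), MISSING, dtype=np.int8)
    for sid, yr, sv, code in hist[["site_id", "year", "survey", "code"]].itertuples(index=False):
        obs[site_index[str(sid)], int(yr) - y0, int(sv) - 1] = int(code)

    site_cov = site_cov.copy()
    site_cov["site_id"] = site_cov["site_id"].astype(str)
    site_cov = site_cov.set_index("site_id").reindex(site_ids)
    depth_class = site_cov["depth_class"].to_numpy(dtype=float)
    veg_ave = site_cov["veg_ave"].to_numpy(dtype=float)

    site_year = {}
    sy_cov = sy_cov.copy()
    sy_cov["site_id"] = sy_cov["site_id"].astype(str)
    value_cols = [c for c in sy_cov.columns if c not in ("site_id", "year")]
    rows = sy_cov["site_id"].map(site_index).to_numpy()
    cols = sy_cov["year"].to_numpy(dtype=int) - y0
    for col in value_cols:
        name = "RO" if col == "runoff" else ("RO_lag1" if col == "runoff_lag1" else col)
        arr = np.full((len(site_ids), len(years)), np.nan)
        arr[rows, cols] = sy_cov[col].to_numpy(dtype=float)
        site_year[name] = arr
    return StudyData(site_ids, years, obs, depth_class, veg_ave, site_year)


def validate_study_data(data: StudyData) -> ValidationReport:
    """Check the structural invariants of a :class:`StudyData`.

    Errors: a site-year mixing code 0 with codes 1/2 (water detection is
    perfect, so a dry observation cannot co-occur with a wet one); non-finite
    or out-of-range covariates.  Warnings: sites surveyed in fewer than two
    distinct years, which are flagged for exclusion.
    """
    report = ValidationReport()
    surveyed = (data.obs != MISSING).any(axis=2)          # (n_sites, T)
    has_dry = (data.obs == 0).any(axis=2)
    has_wet = ((data.obs == 1) | (data.obs == 2)).any(axis=2)
    for i, j in zip(*np.nonzero(has_dry & has_wet)):
        report.errors.append((data.site_ids[i], int(data.years[j]),
                              "site-year mixes dry (0) and wet (1/2) observations"))

    if not np.all(np.isin(data.depth_class, [1, 2, 3, 4])):
        for i in np.nonzero(~np.isin(data.depth_class, [1, 2, 3, 4]))[0]:
            report.errors.append((data.site_ids[i], None,
                                  f"depth_class {data.depth_class[i]} not in 1..4"))
    for i in np.nonzero(~np.isfinite(data.veg_ave) | (data.veg_ave < 0)
                        | (data.veg_ave > 100))[0]:
        report.errors.append((data.site_ids[i], None, "veg_ave outside [0, 100]"))
    if "veg" in data.site_year:
        veg = data.site_year["veg"]
        bad = np.isfinite(veg) & ((veg < 0) | (veg > 100))
        for i, j in zip(*np.nonzero(bad)):
            report.errors.append((data.site_ids[i], int(data.years[j]),
                                  "veg outside [0, 100]"))

    n_years_surveyed = surveyed.sum(axis=1)
    single = n_years_surveyed < 2
    for i in np.nonzero(single)[0]:
        report.warnings.append((data.site_ids[i], None,
                                "surveyed in <2 distinct years; excluded"))
        report.excluded_sites.append(data.site_ids[i])
    report.n_sites_dropped = int(single.sum())
    report.n_sites_retained = data.n_sites - report.n_sites_dropped
    return report


def apply_exclusions(data: StudyData, report: ValidationReport) -> StudyData:
    keep = ~np.isin(data.site_ids, report.excluded_sites)
    return data.subset(keep)


def aggregate_climate(monthly: pd.DataFrame, window=None, mode: str = "sum-over-window"
                      ) -> pd.DataFrame:
    """Aggregate a site × month table to per-site-year covariate totals.

    ``monthly`` has columns ``site_id, year, month, value``.  In
    ``sum-over-window`` mode the months in ``window`` (e.g. ``{4, 5, 6}`` for
    April–June) are summed and each must be present; ``annual-sum`` sums all
    twelve months.
    """
    if mode == "annual-sum":
        window = set(range(1, 13))
    elif mode != "sum-over-window":
        raise ValueError(f"unknown mode {mode!r}")
    if not window:
        raise ValueError("empty month window")
    window = set(int(m) for m in window)
    sub = monthly[monthly["month"].isin(window)]
    counts = sub.groupby(["site_id", "year"])["month"].nunique()
    short = counts[counts < len(window)]
    if len(short):
        sid, yr = short.index[0]
        raise DataError(f"site {sid} year {yr}: missing month in window {sorted(window)}")
    out = (sub.groupby(["site_id", "year"])["value"].sum()
           .rename("total").reset_index())
    return out


def screen_collinearity(covariates: pd.DataFrame, threshold: float = 0.60):
    """Flag covariate pairs whose Pearson |r| meets the (inclusive) threshold.

    Returns a list of ``(name_a, name_b, r)`` over complete cases; a constant
    covariate yields an undefined r (NaN) and the pair is flagged for review.
    """
    names = [c for c in covariates.columns if c not in ("site_id", "year")]
    flagged = []
    for a_idx, a in enumerate(names):
        for b in names[a_idx + 1:]:
            pair = covariates[[a, b]].dropna()
            if len(pair) < 3:
                raise DataError(f"fewer than 3 complete cases for ({a}, {b})")
            x, y = pair[a].to_numpy(float), pair[b].to_numpy(float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                flagged.append((a, b, float("nan")))
                continue
            r = float(np.corrcoef(x, y)[0, 1])
            if abs(r) >= threshold:
                flagged.append((a, b, r))
    return flagged


def export_mark_histories(data: StudyData, path) -> None:
    """Write Program MARK-style encounter histories.

    One line per site: the per-year survey codes concatenated in year order
    ("." for a missing survey), a space, the frequency 1 and a terminal ";".
    """
    with open(path, "w") as fh:
        for i in range(data.n_sites):
            chars = []
            for j in range(data.n_years):
                for k in range(data.n_surveys):
                    c = data.obs[i, j, k]
                    chars.append("." if c == MISSING else str(int(c)))
            fh.write(f"/* {data.site_ids[i]} */ {''.join(chars)} 1;\n")


def import_mark_histories(path, n_surveys: int = 2) -> tuple:
    """Read an exported MARK history file back to (site_ids, obs array)."""
    site_ids, rows = [], []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("/*"):
                comment_end = line.index("*/")
                site_ids.append(line[2:comment_end].strip())
                line = line[comment_end + 2:].strip()
            body = line.rstrip(";").rsplit(None, 1)[0]
            rows.append([MISSING if ch == "." else int(ch) for ch in body])
    obs = np.array(rows, dtype=np.int8)
    T = obs.shape[1] // n_surveys
    return np.array(site_ids), obs.reshape(len(rows), T, n_surveys)


def write_study_data(data: StudyData, history_path, site_covar_path,
                     site_year_covar_path) -> None:
    """Write a StudyData back to the three tidy CSVs (inverse of read)."""
    recs = []
    for i in range(data.n_sites):
        for j in range(data.n_years):
            for k in range(data.n_surveys):
                c = data.obs[i, j, k]
                if c != MISSING:
                    recs.append((data.site_ids[i], int(data.years[j]), k + 1, int(c)))
    pd.DataFrame(recs, columns=["site_id", "year", "survey", "code"]).to_csv(
        history_path, index=False)
    pd.DataFrame({"site_id": data.site_ids, "depth_class": data.depth_class,
                  "veg_ave": data.veg_ave}).to_csv(site_covar_path, index=False)
    base = {"RO": "runoff", "RO_lag1": "runoff_lag1"}
    cols = {"site_id": np.repeat(data.site_ids, data.n_years),
            "year": np.tile(data.years, data.n_sites)}
    for name, arr in data.site_year.items():
        cols[base.get(name, name)] = arr.ravel()
    pd.DataFrame(cols).to_csv(site_year_covar_path, index=False)
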