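"""Detection-history construction and survey-effort accounting.

Daily camera records are first laid out as a sites x days binary matrix
(deployment-relative day index), then collapsed into multi-day sampling
occasions. Missing cells (camera inactive) are carried explicitly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

MISSING = np.nan


@dataclass
class DetectionMatrix:
    """Sites x occasions binary detection history.

    ``values`` is a float array with entries in {0, 1, NaN}; NaN marks an
    occasion in which the camera was never active. Row order follows the
    deployment table.
    """

    site_ids: list[str]
    occasions: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.site_ids), len(self.occasions)):
            raise ValueError("values shape does not match labels")
        ok = np.isnan(self.values) | (self.values == 0) | (self.values == 1)
        if not ok.all():
            raise ValueError("entries must be 0, 1 or missing (NaN)")

    @property
    def n_sites(self) -> int:
        return len(self.site_ids)

    @property
    def n_occasions(self) -> int:
        return len(self.occasions)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.site_ids, columns=self.occasions)

    def write_csv(self, path) -> None:
        out = self.to_frame()
        out.insert(0, "site_id", out.index)
        out.to_csv(path, index=False, na_rep="NA", float_format="%g")

    @classmethod
    def read_csv(cls, path) -> "DetectionMatrix":
        df = pd.read_csv(path, na_values=["NA"]).set_index("site_id")
        return cls(
            site_ids=[str(s) for s in df.index],
            occasions=list(df.columns),
            values=df.to_numpy(dtype=float),
        )


def _deployment_frame(deployments: pd.DataFrame) -> pd.DataFrame:
    dep = deployments.copy()
    dep["start_date"] = pd.to_datetime(dep["start_date"])
    dep["end_date"] = pd.to_datetime(dep["end_date"])
    if (dep["end_date"] < dep["start_date"]).any():
        bad = dep.loc[dep["end_date"] < dep["start_date"], "site_id"].tolist()
        raise ValueError(f"inverted deployment window(s) at site(s): {bad}")
    dep["n_days"] = (dep["end_date"] - dep["start_date"]).dt.days + 1
    return dep


def build_daily_matrix(
    records: pd.DataFrame, deployments: pd.DataFrame, species: str
) -> DetectionMatrix:
    """Sites x days binary matrix: 1 iff >=1 record of ``species`` that day.

    Day columns are deployment-relative (day_1 = each site's own start date).
    Days beyond a site's active window are missing. Records dated outside
    their site's window, or at unknown sites, are rejected with the
    offending rows listed.
    """
    dep = _deployment_frame(deployments)
    site_ids = [str(s) for s in dep["site_id"]]
    n_days_max = int(dep["n_days"].max())
    start = dict(zip(site_ids, dep["start_date"]))
    n_days = dict(zip(site_ids, dep["n_days"]))

    values = np.full((len(site_ids), n_days_max), MISSING)
    for i, sid in enumerate(site_ids):
        values[i, : n_days[sid]] = 0.0

    rec = records[records["species"] == species] if len(records) else records
    if len(rec):
        unknown = sorted(set(rec["site_id"].astype(str)) - set(site_ids))
        if unknown:
            raise ValueError(f"records at unknown site(s): {unknown}")
        row_of = {sid: i for i, sid in enumerate(site_ids)}
        dates = pd.to_datetime(rec["date"])
        bad_rows = []
        for idx, sid, date in zip(rec.index, rec["site_id"].astype(str), dates):
            day = (date - start[sid]).days
            if day < 0 or day >= n_days[sid]:
                bad_rows.append(idx)
            else:
                values[row_of[sid], day] = 1.0
        if bad_rows:
            raise ValueError(
                f"record(s) outside deployment window at rows: {bad_rows}"
            )

    occasions = [f"day_{j + 1}" for j in range(n_days_max)]
    return DetectionMatrix(site_ids=site_ids, occasions=occasions, values=values)


def collapse_occasions(daily: DetectionMatrix, bin_days: int) -> DetectionMatrix:
    """Group consecutive day columns into ``bin_days``-day sampling occasions.

    An occasion is 1 if any day in the bin is 1, 0 if at least one day was
    observed and none detected, and missing only if every day in the bin is
    missing. Bins are anchored at each site's deployment start (column 1).
    """
    if bin_days < 1:
        raise ValueError("bin_days must be >= 1")
    n_days = daily.n_occasions
    n_occ = math.ceil(n_days / bin_days)
    out = np.full((daily.n_sites, n_occ), MISSING)
    for k in range(n_occ):
        block = daily.values[:, k * bin_days : (k + 1) * bin_days]
        observed = ~np.isnan(block)
        any_obs = observed.any(axis=1)
        with np.errstate(invalid="ignore"):
            hit = np.nanmax(np.where(observed, block, 0.0), axis=1)
        out[any_obs, k] = hit[any_obs]
    occasions = [f"occ_{k + 1}" for k in range(n_occ)]
    return DetectionMatrix(site_ids=daily.site_ids, occasions=occasions, values=out)


def effort(deployments: pd.DataFrame) -> int:
    """Total trap nights: sum over sites of active days (inclusive windows)."""
    dep = _deployment_frame(deployments)
    return int(dep["n_days"].sum())


def naive_occupancy(matrix: DetectionMatrix) -> tuple[int, float]:
    """(number of sites with >=1 detection, that number / total sites)."""
    if matrix.n_sites == 0:
        raise ValueError("empty detection matrix")
    detected = np.nansum(np.nan_to_num(matrix.values), axis=1) > 0
    count = int(detected.sum())
    return count, count / matrix.n_sites
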