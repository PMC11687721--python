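"""Model-covariate preparation.

Standardization (z-scores with sample SD), Pearson collinearity screening,
and derivation of the pooled large-predator activity covariate from
carnivore camera records.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: Canonical covariate order. This order defines the layout of the slope
#: vector (after the intercept) everywhere in the package.
CANONICAL_COVARIATES: tuple[str, ...] = (
    "settlement",
    "livestock",
    "predators",
    "cropland",
    "canopycover",
    "human",
    "road",
)

#: Mapping from canonical model covariate names to raw site-table columns.
SITE_COLUMN_MAP: dict[str, str] = {
    "settlement": "settlement_dist",
    "livestock": "livestock",
    "predators": "predator_rate",
    "cropland": "farmland",
    "canopycover": "canopy",
    "human": "humans",
    "road": "road_dist",
}

DEFAULT_PREDATOR_SPECIES: tuple[str, ...] = ("tiger", "leopard")


@dataclass
class CovariateTable:
    """Standardized per-site covariates plus the raw moments.

    ``data`` is indexed by site_id with one column per covariate, each with
    sample mean 0 and sample SD 1 (ddof=1). ``raw_means``/``raw_sds`` allow
    exact back-transformation.
    """

    data: pd.DataFrame
    raw_means: pd.Series = field(repr=False)
    raw_sds: pd.Series = field(repr=False)

    @property
    def site_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def columns(self) -> list[str]:
        return list(self.data.columns)

    def to_raw(self) -> pd.DataFrame:
        """Invert the standardization."""
        return self.data * self.raw_sds + self.raw_means

    def write_csv(self, path) -> None:
        out = self.data.copy()
        out.insert(0, "site_id", out.index)
        out.to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def read_csv(cls, path) -> "CovariateTable":
        df = pd.read_csv(path).set_index("site_id")
        # stored columns are already standardized; recover moments trivially
        return cls(
            data=df,
            raw_means=pd.Series(0.0, index=df.columns),
            raw_sds=pd.Series(1.0, index=df.columns),
        )


def standardize(raw: pd.DataFrame) -> CovariateTable:
    """Z-score every column of ``raw`` using sample mean and SD (ddof=1).

    ``raw`` must be indexed by site_id (or contain a ``site_id`` column) and
    hold only numeric covariate columns. Constant columns cannot be scaled
    and are rejected by name.
    """
    if "site_id" in raw.columns:
        raw = raw.set_index("site_id")
    if len(raw) < 2:
        raise ValueError("standardization requires at least 2 sites")
    means = raw.mean()
    sds = raw.std(ddof=1)
    constant = [c for c in raw.columns if not np.isfinite(sds[c]) or sds[c] == 0.0]
    if constant:
        raise ValueError(
            f"cannot standardize constant column(s): {', '.join(constant)}"
        )
    z = (raw - means) / sds
    return CovariateTable(data=z, raw_means=means, raw_sds=sds)


def correlation_screen(
    table: CovariateTable | pd.DataFrame, threshold: float = 0.7
) -> list[tuple[tuple[str, str], float]]:
    """Return unordered covariate pairs whose Pearson |r| exceeds ``threshold``.

    An empty list means every predictor is retained.
    """
    df = table.data if isinstance(table, CovariateTable) else table
    if len(df) < 3:
        raise ValueError("correlation screen requires at least 3 sites")
    corr = df.corr(method="pearson")
    cols = list(df.columns)
    flagged = []
    for i in range(len(cols)):
        for j in range(i + 1, len(cols)):
            r = corr.iloc[i, j]
            if abs(r) > threshold:
                flagged.append(((cols[i], cols[j]), float(r)))
    return flagged


def predator_covariate(
    records: pd.DataFrame,
    deployments: pd.DataFrame,
    predator_species: Sequence[str] = DEFAULT_PREDATOR_SPECIES,
    bin_days: int = 7,
) -> pd.Series:
    """Per-site fraction of sampling occasions with >=1 pooled predator record.

    Uses the same deployment-anchored occasion binning as the focal-species
    detection matrix. Species labels never observed in ``records`` trigger a
    warning and are ignored.
    """
    from occucam.detections import build_daily_matrix, collapse_occasions

    if len(predator_species) == 0:
        raise ValueError("predator_species must be nonempty")
    seen = set(records["species"].unique()) if len(records) else set()
    for label in predator_species:
        if label not in seen:
            warnings.warn(
                f"predator species {label!r} has no records; ignoring",
                stacklevel=2,
            )
    pooled = records[records["species"].isin(list(predator_species))].copy()
    pooled["species"] = "__predator__"
    daily = build_daily_matrix(pooled, deployments, species="__predator__")
    occ = collapse_occasions(daily, bin_days=bin_days)
    vals = occ.values
    with np.errstate(invalid="ignore"):
        frac = np.nansum(vals, axis=1) / np.maximum(
            np.sum(~np.isnan(vals), axis=1), 1
        )
    return pd.Series(frac, index=occ.site_ids, name="predators")


def model_frame(
    sites: pd.DataFrame,
    predators: pd.Series | None = None,
    columns: Iterable[str] = CANONICAL_COVARIATES,
) -> pd.DataFrame:
    """Assemble the raw (unstandardized) model covariate frame from a site table.

    ``predators`` overrides the site table's ``predator_rate`` column with an
    empirically derived per-site fraction (see :func:`predator_covariate`).
    """
    if "site_id" in sites.columns:
        sites = sites.set_index("site_id")
    out = pd.DataFrame(index=sites.index)
    for name in columns:
        if name == "predators" and predators is not None:
            out[name] = predators.reindex(sites.index).to_numpy(dtype=float)
        else:
            out[name] = sites[SITE_COLUMN_MAP[name]].to_numpy(dtype=float)
    return out
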