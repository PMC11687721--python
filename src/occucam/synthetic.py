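"""Synthetic camera-trap study generator.

Emulates a single-season deployment design: a planar landscape of sites
with a minimum pairwise separation, per-site habitat/disturbance covariates
drawn to match requested means and SDs, latent occupancy states from a
logit-linear model on standardized covariates, and daily detection records
(focal species plus the two large predators) that downstream stages collapse
into occasion-level histories.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import expit

from occucam.covariates import CANONICAL_COVARIATES, model_frame, standardize

#: Default per-covariate (mean, SD) targets for the generated landscape.
#: Canopy in percent, counts are whole-deployment totals, distances in
#: meters, farmland in m^2 within a 500 m buffer, predator_rate an
#: occasion-level detection fraction.
DEFAULT_MOMENTS: dict[str, tuple[float, float]] = {
    "canopy": (42.19, 21.36),
    "humans": (76.72, 244.55),
    "livestock": (36.74, 102.45),
    "road_dist": (741.69, 1138.91),
    "settlement_dist": (2182.80, 1691.33),
    "farmland": (60000.0, 55000.0),
    "predator_rate": (0.12, 0.15),
}

FOCAL_SPECIES = "porcupine"
PREDATORS = ("tiger", "leopard")
DEFAULT_START_DATE = "2022-12-01"


def _check_moments(moments: Mapping[str, tuple[float, float]]) -> None:
    for name, (mean, sd) in moments.items():
        if sd < 0:
            raise ValueError(f"negative SD for covariate {name!r}: {sd}")


def _truncnorm_matched(mean, sd, lo, hi, n, rng):
    """Truncated-normal draws whose *truncated* mean/SD match the targets.

    Solves for the parent (mu, sigma) so that truncation to [lo, hi] leaves
    the requested first two moments intact.
    """
    if sd == 0:
        return np.full(n, float(mean))

    def resid(theta):
        mu, log_sig = theta
        sig = np.exp(log_sig)
        a, b = (lo - mu) / sig, (hi - mu) / sig
        m, v = stats.truncnorm.stats(a, b, loc=mu, scale=sig, moments="mv")
        return [m - mean, np.sqrt(v) - sd]

    sol = optimize.root(resid, x0=[mean, np.log(sd)], method="hybr")
    mu, sig = sol.x[0], float(np.exp(sol.x[1]))
    if not sol.success:  # fall back to naive parameters; range still enforced
        mu, sig = mean, sd
    a, b = (lo - mu) / sig, (hi - mu) / sig
    return stats.truncnorm.rvs(a, b, loc=mu, scale=sig, size=n, random_state=rng)


def _negbin(mean, sd, n, rng):
    """Overdispersed count draws with the requested moments (NB2; Poisson if
    the variance does not exceed the mean)."""
    if sd == 0:
        return np.full(n, float(mean))
    var = sd**2
    if var <= mean:
        return rng.poisson(mean, size=n).astype(float)
    r = mean**2 / (var - mean)
    p = r / (r + mean)
    return rng.negative_binomial(r, p, size=n).astype(float)


def _gamma(mean, sd, n, rng):
    if sd == 0:
        return np.full(n, float(mean))
    shape = (mean / sd) ** 2
    scale = sd**2 / mean
    return rng.gamma(shape, scale, size=n)


def _lognormal(mean, sd, n, rng):
    if sd == 0:
        return np.full(n, float(mean))
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2
    return rng.lognormal(mu, np.sqrt(sigma2), size=n)


def _beta_moments(mean, sd, n, rng):
    if sd == 0:
        return np.full(n, float(mean))
    var = min(sd**2, mean * (1 - mean) * 0.999)
    k = mean * (1 - mean) / var - 1
    return rng.beta(mean * k, (1 - mean) * k, size=n)


def _poisson_disk(n, min_sep, rng):
    """Dart-throwing placement with a guaranteed minimum separation."""
    side = max(np.sqrt(n) * 2.5 * min_sep, 10 * min_sep)
    pts: list[tuple[float, float]] = []
    attempts = 0
    while len(pts) < n:
        x, y = rng.uniform(0, side, size=2)
        if all((x - px) ** 2 + (y - py) ** 2 >= min_sep**2 for px, py in pts):
            pts.append((x, y))
        attempts += 1
        if attempts > 200 * n and len(pts) < n:
            side *= 1.5  # grow the domain rather than loop forever
            attempts = 0
    arr = np.asarray(pts)
    return arr[:, 0], arr[:, 1]


def simulate_landscape(
    n_sites: int,
    seed: int,
    moments: Mapping[str, tuple[float, float]] | None = None,
    min_separation: float = 1000.0,
) -> pd.DataFrame:
    """Generate a site table with covariates matching the requested moments.

    Canopy uses a moment-matched truncated normal on [0, 100]; human and
    livestock totals use a negative binomial (their SDs far exceed their
    means); distances use gamma draws; farmland a log-normal capped at the
    500 m-buffer area; predator activity a beta draw. All draws are
    deterministic given ``seed``.
    """
    if n_sites < 2:
        raise ValueError("n_sites must be >= 2")
    mom = dict(DEFAULT_MOMENTS)
    if moments:
        mom.update(moments)
    _check_moments(mom)
    rng = np.random.default_rng(seed)

    x, y = _poisson_disk(n_sites, min_separation, rng)
    canopy = _truncnorm_matched(*mom["canopy"], 0.0, 100.0, n_sites, rng)
    humans = _negbin(*mom["humans"], n_sites, rng)
    livestock = _negbin(*mom["livestock"], n_sites, rng)
    road = _gamma(*mom["road_dist"], n_sites, rng)
    settlement = _gamma(*mom["settlement_dist"], n_sites, rng)
    farmland = np.minimum(
        _lognormal(*mom["farmland"], n_sites, rng), np.pi * 500.0**2
    )
    predator_rate = np.clip(_beta_moments(*mom["predator_rate"], n_sites, rng), 0, 1)

    sites = pd.DataFrame(
        {
            "site_id": [f"S{i + 1:03d}" for i in range(n_sites)],
            "x": x,
            "y": y,
            "canopy": canopy,
            "humans": humans,
            "livestock": livestock,
            "farmland": farmland,
            "road_dist": road,
            "settlement_dist": settlement,
            "predator_rate": predator_rate,
            "in_protected_area": x < np.median(x),
        }
    )
    return sites


def simulate_truth(
    sites: pd.DataFrame,
    beta: Sequence[float],
    p: float,
    seed: int,
) -> pd.DataFrame:
    """Latent occupancy truth per site.

    ``beta`` is the intercept followed by slopes in the canonical covariate
    order; the linear predictor is evaluated on standardized covariates.
    Returns site_id, psi_true, z_true, p_true (plus predator_rate carried
    through for record simulation).
    """
    beta = np.asarray(beta, dtype=float)
    expected = 1 + len(CANONICAL_COVARIATES)
    if beta.shape != (expected,):
        raise ValueError(
            f"beta must have length {expected}: intercept then slopes in order "
            f"{list(CANONICAL_COVARIATES)}"
        )
    if not 0.0 < p < 1.0:
        raise ValueError("p must lie in (0, 1)")
    raw = model_frame(sites)
    if (raw.std(ddof=1) == 0).any():
        z = (raw - raw.mean()).to_numpy()  # degenerate landscape: center only
        sd = raw.std(ddof=1).to_numpy()
        z = np.divide(z, sd, out=np.zeros_like(z), where=sd > 0)
    else:
        z = standardize(raw).data.to_numpy()
    eta = beta[0] + z @ beta[1:]
    psi = expit(eta)
    rng = np.random.default_rng(seed)
    z_true = rng.binomial(1, psi)
    sid = sites["site_id"] if "site_id" in sites.columns else sites.index
    return pd.DataFrame(
        {
            "site_id": np.asarray(sid, dtype=object),
            "psi_true": psi,
            "z_true": z_true,
            "p_true": float(p),
            "predator_rate": sites["predator_rate"].to_numpy()
            if "predator_rate" in sites.columns
            else 0.0,
        }
    )


def _daily_rate(occasion_p: np.ndarray, bin_days: int) -> np.ndarray:
    # q solves 1 - (1 - q)^bin_days = p, so a full bin detects at rate p
    return 1.0 - np.power(1.0 - occasion_p, 1.0 / bin_days)


def simulate_records(
    truth: pd.DataFrame,
    n_days: int,
    seed: int,
    bin_days: int = 7,
    start_date: str = DEFAULT_START_DATE,
) -> pd.DataFrame:
    """Daily detection records for the focal species and the two predators.

    Occupied sites detect the focal species each day with the daily rate
    whose ``bin_days``-day aggregate equals ``p_true``; unoccupied sites
    produce no focal records (no false positives). Predator records arise
    at each site's ``predator_rate`` (occasion scale), split between tiger
    and leopard.
    """
    if n_days < 1:
        raise ValueError("n_days must be >= 1")
    rng = np.random.default_rng(seed)
    start = pd.Timestamp(start_date)
    dates = pd.date_range(start, periods=n_days, freq="D")

    q_focal = _daily_rate(truth["p_true"].to_numpy(dtype=float), bin_days)
    q_pred = _daily_rate(
        np.clip(truth["predator_rate"].to_numpy(dtype=float), 0.0, 0.999999),
        bin_days,
    )
    z = truth["z_true"].to_numpy(dtype=int)
    site_ids = truth["site_id"].to_numpy(dtype=object)

    rows: list[tuple] = []
    n = len(truth)
    focal_hits = rng.random((n, n_days)) < q_focal[:, None]
    focal_hits &= z[:, None].astype(bool)
    pred_hits = rng.random((n, n_days)) < q_pred[:, None]
    pred_pick = rng.random((n, n_days)) < 0.5  # True -> tiger
    for i in range(n):
        for j in range(n_days):
            d = dates[j].date().isoformat()
            if focal_hits[i, j]:
                rows.append((site_ids[i], d, FOCAL_SPECIES, 1))
            if pred_hits[i, j]:
                rows.append((site_ids[i], d, PREDATORS[0] if pred_pick[i, j] else PREDATORS[1], 1))
    return pd.DataFrame(rows, columns=["site_id", "date", "species", "count"])


def make_deployments(
    site_ids: Sequence[str],
    n_days: int,
    start_date: str = DEFAULT_START_DATE,
) -> pd.DataFrame:
    """Deployment table with every site active for the same inclusive window."""
    if n_days < 1:
        raise ValueError("n_days must be >= 1")
    start = pd.Timestamp(start_date)
    end = start + pd.Timedelta(days=n_days - 1)
    return pd.DataFrame(
        {
            "site_id": list(site_ids),
            "start_date": start.date().isoformat(),
            "end_date": end.date().isoformat(),
        }
    )


def write_study(
    outdir,
    sites: pd.DataFrame,
    deployments: pd.DataFrame,
    records: pd.DataFrame,
) -> None:
    """Write the three raw-study CSVs (sites, deployments, records)."""
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    sites.to_csv(out / "sites.csv", index=False, float_format="%.17g")
    deployments.to_csv(out / "deployments.csv", index=False)
    records.to_csv(out / "records.csv", index=False)
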