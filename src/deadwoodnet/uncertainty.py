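"""Monte-Carlo engine for price, discount-rate and storm uncertainty.

Three uncertainty sources perturb regime NPVs:

* wood prices follow a driftless geometric Brownian motion whose yearly
  log-return volatility is estimated from a price history (with
  neighbour-assortment substitution for implausibly volatile series);
* the discount rate is a risk-free 0.67% plus a truncated exponential
  spread mapped onto [0.0067, 0.03];
* storms occur in any simulation year with the annual occurrence
  probability of a Lothar-strength wind speed (41.67 m/s) under a Gumbel
  model of yearly maxima; a storm damages each stand according to a
  logistic damage model of its mean tree and depresses prices by 25% in
  the period of occurrence.

Scenario NPVs feed both the plan evaluation and the covariance model of
the robust optimization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import gumbel_r

from .synth import Landscape, n_periods_of

# ---------------------------------------------------------------------------
# price volatility and GBM paths


def estimate_volatility(
    history: pd.DataFrame,
    cap: float = 0.20,
    assortment_order: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Yearly log-return volatility per species x assortment.

    When a series' volatility exceeds ``cap`` (a guard against implausible
    long-horizon price excursions), the volatility of the nearest larger
    assortment class below the cap is substituted; if none qualifies the
    nearest smaller one is used, and as a last resort the cap itself.
    """
    if assortment_order is None:
        assortment_order = tuple(dict.fromkeys(history["assortment_class"]))
    rows = []
    for sp, g in history.groupby("species", sort=False):
        sig: dict[str, float] = {}
        for a in assortment_order:
            series = g[g["assortment_class"] == a].sort_values("year")["price"].to_numpy()
            if len(series) < 2:
                raise ValueError(f"need >= 2 yearly prices for {sp}/{a}")
            if np.any(series <= 0):
                raise ValueError("prices must be positive")
            lr = np.diff(np.log(series))
            sig[a] = float(np.std(lr, ddof=1)) if len(lr) > 1 else 0.0
        for idx, a in enumerate(assortment_order):
            raw = sig[a]
            used, sub = raw, False
            if raw > cap:
                sub = True
                larger = [sig[b] for b in assortment_order[idx + 1 :] if sig[b] <= cap]
                smaller = [sig[b] for b in reversed(assortment_order[:idx]) if sig[b] <= cap]
                used = larger[0] if larger else (smaller[0] if smaller else cap)
            rows.append(
                {
                    "species": sp,
                    "assortment_class": a,
                    "sigma_raw": raw,
                    "sigma": used,
                    "substituted": sub,
                }
            )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class GBMSpec:
    initial_price: float
    sigma: float
    horizon_years: int = 50
    n_paths: int = 100

    def __post_init__(self):
        if self.sigma < 0:
            raise ValueError("volatility must be non-negative")
        if self.initial_price <= 0:
            raise ValueError("initial price must be positive")


def simulate_price_paths(spec: GBMSpec, seed: int = 0) -> np.ndarray:
    """Driftless GBM paths, shape (n_paths, horizon+1); column 0 is P0."""
    rng = np.random.default_rng(seed)
    incr = rng.normal(0.0, spec.sigma, size=(spec.n_paths, spec.horizon_years))
    x = np.concatenate([np.zeros((spec.n_paths, 1)), np.cumsum(incr, axis=1)], axis=1)
    return spec.initial_price * np.exp(x)


# ---------------------------------------------------------------------------
# discount rates


@dataclass(frozen=True)
class DiscountRateSpec:
    risk_free: float = 0.0067
    exp_rate: float = 3.5
    upper_rate: float = 0.03
    truncation_quantile: float = 0.999

    def __post_init__(self):
        if self.risk_free >= self.upper_rate:
            raise ValueError("risk-free rate must lie below the upper rate")
        if self.exp_rate <= 0:
            raise ValueError("exponential rate parameter must be positive")


def sample_discount_rates(spec: DiscountRateSpec, n: int, seed: int = 0) -> np.ndarray:
    """Rates in [risk_free, upper_rate], denser near the risk-free end.

    An Exp(rate) deviate truncated at its 99.9% quantile is rescaled onto
    the spread between the risk-free and the upper rate.
    """
    rng = np.random.default_rng(seed)
    e = rng.exponential(1.0 / spec.exp_rate, size=n)
    q = -np.log(1.0 - spec.truncation_quantile) / spec.exp_rate
    e = np.minimum(e, q)
    return spec.risk_free + (e / q) * (spec.upper_rate - spec.risk_free)


# ---------------------------------------------------------------------------
# storms


def fit_gumbel(series: np.ndarray) -> tuple[float, float]:
    """Maximum-likelihood Gumbel (type-I extreme value) fit to yearly maxima."""
    x = np.asarray(series, dtype=float)
    if x.size < 10:
        raise ValueError("need at least 10 yearly maxima")
    if np.std(x) == 0:
        raise ValueError("degenerate (zero-variance) wind series")
    mu, s = gumbel_r.fit(x)
    return float(mu), float(s)


def annual_occurrence_probability(x: float, mu: float, s: float) -> float:
    """P(yearly maximum exceeds x) under Gumbel(mu, s)."""
    if s <= 0:
        raise ValueError("scale must be positive")
    return float(1.0 - np.exp(-np.exp(-(x - mu) / s)))


DEFAULT_DAMAGE_COEFFS = {
    # species: (beta1, alpha, gamma); damage rises with height, falls with DBH
    "spruce": (-1.0, -1.8, 2.2),
    "silver_fir": (-1.5, -1.8, 2.2),
    "beech": (-2.1, -1.8, 2.2),
    "oak": (-2.5, -1.8, 2.2),
}

DEFAULT_TOPEX_BETAS = (0.0, 0.25, 0.5, 0.8)  # classes 1..4


@dataclass(frozen=True)
class StormModel:
    gumbel_mu: float
    gumbel_s: float
    reference_speed: float = 41.67  # m/s, storm "Lothar"
    damage_coeffs: dict = field(default_factory=lambda: dict(DEFAULT_DAMAGE_COEFFS))
    topex_betas: tuple[float, float, float, float] = DEFAULT_TOPEX_BETAS
    storm_center: tuple[float, float] = (0.0, 0.0)
    smoothing_amplitude: float = 0.8
    smoothing_range_m: float = 3000.0
    price_shock_factor: float = 0.75
    aop_override: float | None = None  # forces the occurrence probability

    @property
    def aop(self) -> float:
        if self.aop_override is not None:
            return float(self.aop_override)
        return annual_occurrence_probability(self.reference_speed, self.gumbel_mu, self.gumbel_s)


def storm_damage_fraction(
    dbh_cm: float,
    height_m: float,
    topex_class: int,
    species: str,
    model: StormModel,
    location: tuple[float, float] | None = None,
) -> float:
    """Damaged share of a stand given its mean tree, via the logistic model.

    The linear predictor is b1 + log(DBH^a / h^-g) + topex-class effect +
    a radially decaying term in the distance to the storm centre; the
    damage probability of the mean tree is used directly as the damaged
    share of the stand.
    """
    if dbh_cm <= 0 or height_m <= 0:
        raise ValueError("DBH and height must be positive")
    b1, alpha, gamma = model.damage_coeffs[species]
    g = b1 + alpha * np.log(dbh_cm) + gamma * np.log(height_m)
    g += model.topex_betas[int(topex_class) - 1]
    if location is not None:
        d = float(np.hypot(location[0] - model.storm_center[0], location[1] - model.storm_center[1]))
        g += model.smoothing_amplitude * np.exp(-d / model.smoothing_range_m)
    return float(expit(g))


# ---------------------------------------------------------------------------
# scenario engine


@dataclass
class ScenarioSet:
    """Monte-Carlo NPV matrix per managed (stand, regime) pair.

    ``npv`` has shape (n_stands, n_regimes, n_scenarios); ``labels`` holds
    one row per scenario (trajectory, price-path id, discount rate, storm
    years).
    """

    stand_ids: list[int]
    regime_ids: list[int]
    npv: np.ndarray
    labels: pd.DataFrame
    seed: int

    @property
    def n_scenarios(self) -> int:
        return self.npv.shape[2]

    def stand_index(self) -> dict[int, int]:
        return {s: i for i, s in enumerate(self.stand_ids)}

    def regime_index(self) -> dict[int, int]:
        return {r: i for i, r in enumerate(self.regime_ids)}

    def expected_npv(self) -> pd.DataFrame:
        """Scenario-mean NPV per (stand, regime), pooled over trajectories."""
        m = self.npv.mean(axis=2)
        rows = [
            {"stand_id": s, "regime_id": r, "enpv": float(m[i, j])}
            for i, s in enumerate(self.stand_ids)
            for j, r in enumerate(self.regime_ids)
        ]
        return pd.DataFrame(rows)

    def to_long_frame(self) -> pd.DataFrame:
        recs = []
        for i, s in enumerate(self.stand_ids):
            for j, r in enumerate(self.regime_ids):
                for k in range(self.n_scenarios):
                    recs.append((s, r, k, float(self.npv[i, j, k])))
        df = pd.DataFrame(recs, columns=["stand_id", "regime_id", "scenario", "npv"])
        return df.merge(
            self.labels.rename_axis("scenario").reset_index(), on="scenario", how="left"
        )


def simulate_scenarios(
    landscape: Landscape,
    outcomes: pd.DataFrame,
    sigma_by_species: dict,
    rate_spec: DiscountRateSpec,
    storm_model: StormModel,
    n_per_trajectory: int = 100,
    seed: int = 0,
    period_years: int = 10,
    retention_corrections: pd.DataFrame | None = None,
) -> ScenarioSet:
    """Scenario NPVs combining price paths, discount rates and storms.

    Per scenario: one discount-rate draw, one driftless GBM multiplier
    path per species, and yearly storm draws.  A storm damages each stand
    by its mean-tree damage probability; the damaged share reduces
    harvested and standing volumes in the period of occurrence and all
    later periods, and depresses prices by the shock factor in the period
    of occurrence.  ``retention_corrections`` (stand_id, regime_id,
    trajectory, correction EUR) is added to every scenario NPV of the
    pair when provided.
    """
    rng = np.random.default_rng(seed)
    n_periods = n_periods_of(outcomes)
    horizon = n_periods * period_years
    trajectories = list(dict.fromkeys(outcomes["trajectory"]))
    landscape_ids = {s.id for s in landscape.stands}
    stray = set(outcomes["stand_id"].unique()) - landscape_ids
    if stray:
        raise ValueError(f"outcome rows reference unknown stands: {sorted(stray)}")
    stand_ids = sorted(outcomes["stand_id"].unique())
    regime_ids = sorted(outcomes["regime_id"].unique())
    ns, nr_, npd = len(stand_ids), len(regime_ids), n_periods
    s_index = {s: i for i, s in enumerate(stand_ids)}
    r_index = {r: i for i, r in enumerate(regime_ids)}
    by_id = {s.id: s for s in landscape.stands}
    species_list = sorted({by_id[s].dominant_species for s in stand_ids})
    stand_species_idx = np.array(
        [species_list.index(by_id[s].dominant_species) for s in stand_ids]
    )

    corr = np.zeros((ns, nr_, len(trajectories)))
    if retention_corrections is not None:
        t_index = {t: i for i, t in enumerate(trajectories)}
        for _, row in retention_corrections.iterrows():
            corr[
                s_index[int(row["stand_id"])],
                r_index[int(row["regime_id"])],
                t_index[row["trajectory"]],
            ] = float(row["correction"])

    # pack outcome tables per trajectory
    rev = np.zeros((len(trajectories), ns, nr_, npd))
    ini_val = np.zeros((len(trajectories), ns, nr_))
    fin_val = np.zeros((len(trajectories), ns, nr_))
    dbh = np.zeros((len(trajectories), ns, npd))
    hgt = np.zeros((len(trajectories), ns, npd))
    for ti, traj in enumerate(trajectories):
        sub = outcomes[outcomes["trajectory"] == traj]
        for _, row in sub.iterrows():
            i, j = s_index[int(row["stand_id"])], r_index[int(row["regime_id"])]
            ini_val[ti, i, j] = row["ini_stock_value"]
            fin_val[ti, i, j] = row["fin_stock_value"]
            for k in range(npd):
                rev[ti, i, j, k] = row[f"rev_p{k + 1}"]
                dbh[ti, i, k] = row[f"dbh_p{k + 1}"]
                hgt[ti, i, k] = row[f"height_p{k + 1}"]

    aop = storm_model.aop
    total = n_per_trajectory * len(trajectories)
    npv = np.zeros((ns, nr_, total))
    label_rows = []
    year_period = np.arange(1, horizon + 1)
    period_of_year = (year_period - 1) // period_years  # 0-based
    disc_years = period_years * np.arange(1, npd + 1)  # revenue booked at period end

    scen = 0
    for ti, traj in enumerate(trajectories):
        rates = sample_discount_rates(rate_spec, n_per_trajectory, seed=int(rng.integers(2**31)))
        for p in range(n_per_trajectory):
            r = float(rates[p])
            # species price multipliers at period-end years
            mult = np.ones((len(species_list), npd))
            for si, sp in enumerate(species_list):
                sig = float(sigma_by_species.get(sp, 0.0))
                path = np.exp(np.cumsum(rng.normal(0.0, sig, size=horizon)))
                mult[si] = path[disc_years - 1]
            storm_years = year_period[rng.random(horizon) < aop]
            storm_periods = sorted({int(period_of_year[y - 1]) for y in storm_years})
            shock = np.ones(npd)
            surv = np.ones((ns, npd))
            if storm_periods:
                for pk in storm_periods:
                    shock[pk] = storm_model.price_shock_factor
                    for i, sid in enumerate(stand_ids):
                        st = by_id[sid]
                        d = storm_damage_fraction(
                            float(dbh[ti, i, pk]),
                            float(hgt[ti, i, pk]),
                            st.topex_class,
                            st.dominant_species,
                            storm_model,
                            location=st.centroid,
                        )
                        surv[i, pk:] *= 1.0 - d
            discount = (1.0 + r) ** (-(disc_years - 1))
            eff = mult[stand_species_idx][:, None, :] * shock[None, None, :] * surv[:, None, :]
            cash = np.einsum("ijk,ijk,k->ij", rev[ti], eff, discount)
            fin = fin_val[ti] * surv[:, -1][:, None] * (1.0 + r) ** (-(horizon - 1))
            npv[:, :, scen] = -ini_val[ti] + cash + fin + corr[:, :, ti]
            label_rows.append(
                {
                    "trajectory": traj,
                    "path_id": p,
                    "rate": r,
                    "storm_years": ";".join(str(int(y)) for y in storm_years),
                }
            )
            scen += 1
    labels = pd.DataFrame(label_rows)
    return ScenarioSet(stand_ids=stand_ids, regime_ids=regime_ids, npv=npv, labels=labels, seed=seed)


# ---------------------------------------------------------------------------
# covariance model


@dataclass
class CovarianceModel:
    """Per-regime covariance of stand NPVs with PD repair and Cholesky factors."""

    regime_ids: list[int]
    stand_ids: list[int]
    raw: np.ndarray  # (n_regimes, n, n)
    repaired: np.ndarray
    chol: np.ndarray  # lower-triangular factors L with L L^T = repaired


def nearest_positive_definite(a: np.ndarray, rel_floor: float = 1e-12) -> np.ndarray:
    """Eigenvalue-clipping repair to the closest PD matrix (Frobenius sense)."""
    sym = 0.5 * (a + a.T)
    w, v = np.linalg.eigh(sym)
    floor = max(w.max(), 0.0) * rel_floor + np.finfo(float).tiny
    w_clipped = np.maximum(w, floor)
    return (v * w_clipped) @ v.T


def estimate_covariance(scen: ScenarioSet) -> CovarianceModel:
    """Sample covariance of stand NPVs across scenarios, one matrix per regime."""
    if scen.n_scenarios < 2:
        raise ValueError("need at least 2 scenarios")
    ns = len(scen.stand_ids)
    nr_ = len(scen.regime_ids)
    raw = np.zeros((nr_, ns, ns))
    rep = np.zeros_like(raw)
    chol = np.zeros_like(raw)
    for j in range(nr_):
        data = scen.npv[:, j, :]  # (n_stands, n_scen)
        c = np.cov(data)
        c = np.atleast_2d(c)
        raw[j] = c
        rep[j] = nearest_positive_definite(c)
        chol[j] = np.linalg.cholesky(rep[j])
    return CovarianceModel(
        regime_ids=list(scen.regime_ids), stand_ids=list(scen.stand_ids), raw=raw, repaired=rep, chol=chol
    )
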