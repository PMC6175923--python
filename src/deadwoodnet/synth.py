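"""Seeded synthetic landscapes, management-regime outcomes, prices and winds.

The generators replace the raw inputs of the case study this package is
modelled on: a single-tree growth simulator driving per-stand management
outcomes, GIS stand maps, state price lists, and weather-station wind
records.  Everything is drawn from documented distributions behind a single
integer seed so that every downstream analysis is reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import MultiPoint, Polygon, box
from shapely.ops import voronoi_diagram

SPECIES = ("beech", "spruce", "silver_fir", "oak")
TRAJECTORIES = ("RCP2.6", "RCP4.5", "RCP6.0", "RCP8.5")

#: Multiplicative growth modifiers per climate trajectory.  Deliberately
#: non-monotone across forcing intensity: the low-forcing pathway is the
#: least productive and the moderate pathway the most productive.
DEFAULT_TRAJECTORY_MULTIPLIERS = {
    "RCP2.6": 0.92,
    "RCP4.5": 1.00,
    "RCP6.0": 1.10,
    "RCP8.5": 1.04,
}


@dataclass(frozen=True)
class Stand:
    """One management unit (polygon) of the landscape."""

    id: int
    area: float  # hectares
    centroid: tuple[float, float]  # planar metres
    polygon: Polygon
    dominant_species: str
    age: float  # years
    existing_reserve: bool
    topex_class: int  # 1..4 exposure proxy


@dataclass
class Landscape:
    stands: list[Stand]
    bounds: tuple[float, float, float, float]

    @property
    def total_area(self) -> float:
        return float(sum(s.area for s in self.stands))

    @property
    def reserve_area(self) -> float:
        return float(sum(s.area for s in self.stands if s.existing_reserve))

    def stand(self, stand_id: int) -> Stand:
        return self._by_id()[stand_id]

    def _by_id(self) -> dict[int, Stand]:
        return {s.id: s for s in self.stands}

    def managed_stands(self) -> list[Stand]:
        return [s for s in self.stands if not s.existing_reserve]


@dataclass(frozen=True)
class LandscapeConfig:
    """Targets for the synthetic landscape.

    Defaults reproduce the case-study scale: 2,534 ha of forest of which
    145 ha are pre-existing reserves.  ``old_growth_share`` is the share of
    stands generated as old (>160 years) beech/silver-fir, i.e. the pool of
    reserve candidates.
    """

    total_area_ha: float = 2534.0
    reserve_area_ha: float = 145.0
    n_stands: int = 120
    species_mix: dict = field(
        default_factory=lambda: {"beech": 0.40, "spruce": 0.30, "silver_fir": 0.20, "oak": 0.10}
    )
    old_growth_share: float = 0.35
    old_age_range: tuple[float, float] = (165.0, 230.0)
    young_age_range: tuple[float, float] = (30.0, 155.0)
    area_tolerance: float = 0.01  # relative


class ConfigError(ValueError):
    pass


def _voronoi_stand_polygons(rng: np.random.Generator, n: int, side: float) -> list[Polygon]:
    """Perturbed Voronoi tessellation of ``n`` seeded points in a square."""
    # jittered grid seeds avoid slivers while keeping size variety
    g = int(np.ceil(np.sqrt(n)))
    xs, ys = np.meshgrid(np.linspace(0, side, g + 2)[1:-1], np.linspace(0, side, g + 2)[1:-1])
    pts = np.column_stack([xs.ravel(), ys.ravel()])
    pts = pts[rng.permutation(len(pts))[:n]]
    pts = pts + rng.normal(0.0, side / (3.5 * g), size=pts.shape)
    pts = np.clip(pts, side * 1e-3, side * (1 - 1e-3))
    envelope = box(0.0, 0.0, side, side)
    cells = voronoi_diagram(MultiPoint([tuple(p) for p in pts]), envelope=envelope)
    polys: list[Polygon | None] = [None] * n
    cell_list = [c.intersection(envelope) for c in cells.geoms]
    for cell in cell_list:
        if cell.is_empty:
            continue
        d = [cell.distance(shapely.points(p[0], p[1])) for p in pts]
        polys[int(np.argmin(d))] = cell
    out = [p for p in polys if p is not None and p.area > 0]
    return out


def _grow_old_massif(rng: np.random.Generator, polys: list[Polygon], n_old: int) -> np.ndarray:
    """Boolean old-growth mask forming one connected cluster of stands."""
    n = len(polys)
    adj: dict[int, set[int]] = {i: set() for i in range(n)}
    for i in range(n):
        for j in range(i + 1, n):
            inter = polys[i].intersection(polys[j])
            if inter.length >= 1.0:
                adj[i].add(j)
                adj[j].add(i)
    is_old = np.zeros(n, dtype=bool)
    seed_stand = int(rng.integers(n))
    cluster = [seed_stand]
    is_old[seed_stand] = True
    frontier = set(adj[seed_stand])
    while is_old.sum() < n_old and frontier:
        nxt = sorted(frontier)[int(rng.integers(len(frontier)))]
        frontier.discard(nxt)
        is_old[nxt] = True
        cluster.append(nxt)
        frontier |= {v for v in adj[nxt] if not is_old[v]}
    return is_old


def _pick_reserve_subset(
    rng: np.random.Generator,
    areas_ha: np.ndarray,
    candidate_idx: np.ndarray,
    target_ha: float,
    rel_tol: float,
    max_restarts: int = 400,
) -> list[int]:
    """Randomized-greedy subset of candidate stands whose area hits the target.

    Subset sums over a few dozen heterogeneous stand areas are dense enough
    that a greedy pass with random orderings reaches the percent-level
    tolerance quickly; a one-swap improvement pass mops up near-misses.
    """
    tol = rel_tol * max(target_ha, 1e-9)
    best: list[int] | None = None
    best_err = np.inf
    if len(candidate_idx) <= 18:
        # small pools: exhaustive subset search gives the best achievable match
        ids = [int(i) for i in candidate_idx]
        for mask in range(1, 1 << len(ids)):
            total = sum(areas_ha[ids[b]] for b in range(len(ids)) if mask >> b & 1)
            err = abs(total - target_ha)
            if err < best_err:
                best = [ids[b] for b in range(len(ids)) if mask >> b & 1]
                best_err = err
            if best_err <= tol:
                break
        if best_err > tol:
            raise ConfigError(
                f"could not assemble existing reserves of {target_ha} ha within "
                f"{100 * rel_tol:.1f}% from the generated stands"
            )
        return best
    for _ in range(max_restarts):
        order = candidate_idx[rng.permutation(len(candidate_idx))]
        chosen: set[int] = set()
        total = 0.0
        for i in order:
            if total + areas_ha[i] <= target_ha + tol:
                chosen.add(int(i))
                total += areas_ha[i]
        err = abs(total - target_ha)
        # one-swap improvement
        improved = True
        while err > tol and improved:
            improved = False
            outside = [int(i) for i in candidate_idx if int(i) not in chosen]
            for i in sorted(chosen):
                for j in outside:
                    e2 = abs(total - areas_ha[i] + areas_ha[j] - target_ha)
                    if e2 < err - 1e-12:
                        chosen.discard(i)
                        chosen.add(j)
                        total += areas_ha[j] - areas_ha[i]
                        err = e2
                        improved = True
                        break
                if improved:
                    break
        if err < best_err:
            best, best_err = sorted(chosen), err
        if best_err <= tol:
            break
    if best is None or best_err > tol:
        raise ConfigError(
            f"could not assemble existing reserves of {target_ha} ha within "
            f"{100 * rel_tol:.1f}% from the generated stands"
        )
    return best


def generate_landscape(config: LandscapeConfig | None = None, seed: int = 0) -> Landscape:
    """Generate a seeded synthetic stand map.

    Returns a landscape whose total and existing-reserve areas match the
    configured targets within ``config.area_tolerance`` (1% by default).
    Deterministic for a fixed ``(config, seed)`` pair.
    """
    config = config or LandscapeConfig()
    if config.total_area_ha <= 0 or config.n_stands < 4:
        raise ConfigError("total area must be positive and stand count >= 4")
    if config.reserve_area_ha >= config.total_area_ha:
        raise ConfigError("existing-reserve share must be < 100%")
    rng = np.random.default_rng(seed)
    side = float(np.sqrt(config.total_area_ha * 1e4))  # metres
    polys = _voronoi_stand_polygons(rng, config.n_stands, side)
    areas_ha = np.array([p.area / 1e4 for p in polys])

    n = len(polys)
    mix = config.species_mix
    species_names = list(mix.keys())
    probs = np.array([mix[s] for s in species_names], dtype=float)
    probs = probs / probs.sum()

    # Old growth clusters spatially (less accessible terrain escapes
    # harvesting), so grow one contiguous massif on the adjacency graph;
    # this also keeps existing reserves expandable into larger blocks.
    is_old = _grow_old_massif(rng, polys, round(config.old_growth_share * n))
    species = np.array(
        [
            rng.choice(["beech", "silver_fir"], p=[0.7, 0.3])
            if old
            else rng.choice(species_names, p=probs)
            for old in is_old
        ]
    )
    ages = np.where(
        is_old,
        rng.uniform(*config.old_age_range, size=n),
        rng.uniform(*config.young_age_range, size=n),
    )
    topex = rng.integers(1, 5, size=n)

    reserve_ids: list[int] = []
    if config.reserve_area_ha > 0:
        # existing reserves are drawn from the old beech/fir pool, mirroring
        # set-aside practice for old-growth broadleaf stands
        cand = np.where(is_old)[0]
        if cand.size == 0:
            raise ConfigError("no old-growth stands generated to host existing reserves")
        reserve_ids = _pick_reserve_subset(
            rng, areas_ha, cand, config.reserve_area_ha, config.area_tolerance
        )

    stands = []
    for i in range(n):
        c = polys[i].centroid
        stands.append(
            Stand(
                id=i,
                area=float(areas_ha[i]),
                centroid=(float(c.x), float(c.y)),
                polygon=polys[i],
                dominant_species=str(species[i]),
                age=float(ages[i]),
                existing_reserve=i in reserve_ids,
                topex_class=int(topex[i]),
            )
        )
    ls = Landscape(stands=stands, bounds=(0.0, 0.0, side, side))
    if abs(ls.total_area - config.total_area_ha) > config.area_tolerance * config.total_area_ha:
        raise ConfigError("generated total area misses the configured target")
    return ls


# ---------------------------------------------------------------------------
# management-regime outcomes


@dataclass(frozen=True)
class RegimeConfig:
    """Shape of the synthetic management-regime gradient.

    Regime 1 is the no-harvest reference; regimes 2-3 are the continuous
    cover ("Liocourt"/"Meyer") selection systems with flat harvest
    profiles; the remaining regimes form an intensity gradient whose
    higher ranks harvest earlier and more (front-loaded removal profile).
    """

    selection_intensities: tuple[float, float] = (0.10, 0.14)
    gradient_range: tuple[float, float] = (0.18, 0.36)
    early_bias: float = 0.30  # front-loading of the gradient removal profile
    stumpage_factor: float = 0.75  # standing-stock value vs net harvest price
    net_price_eur_m3: dict = field(
        default_factory=lambda: {"beech": 48.0, "spruce": 55.0, "silver_fir": 50.0, "oak": 72.0}
    )
    productivity_m3_ha_yr: dict = field(
        default_factory=lambda: {"beech": 7.5, "spruce": 10.5, "silver_fir": 9.0, "oak": 5.5}
    )


def regime_labels(n_regimes: int) -> list[str]:
    labels = ["no_harvest", "liocourt", "meyer"]
    labels += [f"intensity_{k}" for k in range(1, n_regimes - 2)]
    return labels[:n_regimes]


def regime_intensities(n_regimes: int, config: RegimeConfig) -> np.ndarray:
    lo, hi = config.gradient_range
    grad = np.linspace(lo, hi, max(n_regimes - 3, 1))
    vals = [0.0, *config.selection_intensities, *grad]
    return np.asarray(vals[:n_regimes])


def _removal_profile(label: str, intensity: float, n_periods: int, bias: float) -> np.ndarray:
    """Per-period removal fraction; mean equals ``intensity``."""
    if intensity == 0.0:
        return np.zeros(n_periods)
    if label in ("liocourt", "meyer"):
        w = np.ones(n_periods)
    else:
        # linear front-loading: first period harvests (1+bias)x the mean
        w = 1.0 + bias * np.linspace(1.0, -1.0, n_periods)
    return np.clip(intensity * w, 0.0, 0.95)


def _initial_volume_m3_ha(species: str, age: float) -> float:
    cap = {"beech": 520.0, "spruce": 620.0, "silver_fir": 580.0, "oak": 440.0}[species]
    return cap * (1.0 - np.exp(-age / 80.0))


def generate_regime_outcomes(
    landscape: Landscape,
    n_regimes: int = 8,
    trajectories: tuple[str, ...] = TRAJECTORIES,
    horizon_years: int = 50,
    period_years: int = 10,
    seed: int = 0,
    config: RegimeConfig | None = None,
    trajectory_multipliers: dict | None = None,
) -> pd.DataFrame:
    """Simulate per (stand, regime, trajectory) periodic outcomes.

    A stand carries volume ``V`` (m3) that grows by a fixed site- and
    climate-dependent increment each period; regime ``j`` removes a fraction
    of the post-growth volume following its removal profile.  Because growth
    is additive, mass balance makes cumulative removals monotone in the
    regime intensity rank.  One row per managed stand x regime x trajectory.
    """
    if horizon_years < period_years:
        raise ConfigError("horizon shorter than one period")
    if horizon_years % period_years:
        raise ConfigError("horizon must be divisible by the period length")
    if n_regimes < 3:
        raise ConfigError("need >= 3 regimes (no-harvest plus two selection systems)")
    config = config or RegimeConfig()
    mults = trajectory_multipliers or DEFAULT_TRAJECTORY_MULTIPLIERS
    n_periods = horizon_years // period_years
    labels = regime_labels(n_regimes)
    intensities = regime_intensities(n_regimes, config)
    rng = np.random.default_rng(seed)

    managed = landscape.managed_stands()
    # per-stand site noise, shared across regimes/trajectories
    site = {s.id: float(rng.lognormal(0.0, 0.12)) for s in managed}
    price_noise = {s.id: float(rng.normal(1.0, 0.05)) for s in managed}
    dw_noise = {s.id: float(rng.normal(0.0, 0.1)) for s in managed}

    rows = []
    for stand in managed:
        sp = stand.dominant_species
        v0 = _initial_volume_m3_ha(sp, stand.age) * stand.area
        growth_base = config.productivity_m3_ha_yr[sp] * site[stand.id] * stand.area * period_years
        price = config.net_price_eur_m3[sp] * price_noise[stand.id]
        stump = config.stumpage_factor * price
        for traj in trajectories:
            m = mults[traj]
            growth = growth_base * m
            for j, (label, rho) in enumerate(zip(labels, intensities), start=1):
                f = _removal_profile(label, rho, n_periods, config.early_bias)
                vol = np.zeros(n_periods)
                standvol = np.zeros(n_periods)
                v = v0
                for k in range(n_periods):
                    v_grown = v + growth
                    vol[k] = f[k] * v_grown
                    v = v_grown - vol[k]
                    standvol[k] = v
                rev = vol * price
                age_k = stand.age + period_years * np.arange(1, n_periods + 1)
                dbh = np.minimum(12.0 + 0.42 * age_k, 75.0)
                height = 1.3 + 36.0 * (1.0 - np.exp(-age_k / 45.0)) * m**0.25
                dw = np.clip(
                    0.3 + 1.1 * (1.0 - rho / 0.4) + dw_noise[stand.id], 0.05, None
                ) * np.ones(n_periods)
                row = {
                    "stand_id": stand.id,
                    "regime_id": j,
                    "regime_label": label,
                    "intensity": float(rho),
                    "trajectory": traj,
                    "ini_stock_volume": v0,
                    "fin_stock_volume": float(v),
                    "ini_stock_value": v0 * stump,
                    "fin_stock_value": float(v) * stump,
                }
                for k in range(n_periods):
                    row[f"vol_p{k + 1}"] = float(vol[k])
                    row[f"rev_p{k + 1}"] = float(rev[k])
                    row[f"standvol_p{k + 1}"] = float(standvol[k])
                    row[f"dbh_p{k + 1}"] = float(dbh[k])
                    row[f"height_p{k + 1}"] = float(height[k])
                    row[f"deadwood_p{k + 1}"] = float(dw[k])
                rows.append(row)
    return pd.DataFrame(rows)


def n_periods_of(outcomes: pd.DataFrame) -> int:
    return sum(1 for c in outcomes.columns if c.startswith("vol_p"))


def period_columns(outcomes: pd.DataFrame, prefix: str) -> list[str]:
    n = n_periods_of(outcomes)
    return [f"{prefix}_p{k + 1}" for k in range(n)]


# ---------------------------------------------------------------------------
# prices and winds


ASSORTMENTS = ("pulp", "sawlog_small", "sawlog_large")  # ordered small -> large

DEFAULT_PRICE_LEVELS = {
    "pulp": 28.0,
    "sawlog_small": 62.0,
    "sawlog_large": 95.0,
}

DEFAULT_PRICE_VOLATILITY = {
    "pulp": 0.25,
    "sawlog_small": 0.12,
    "sawlog_large": 0.08,
}


def generate_price_history(
    seed: int = 0,
    species: tuple[str, ...] = SPECIES,
    assortments: tuple[str, ...] = ASSORTMENTS,
    n_years: int = 17,
    levels: dict | None = None,
    volatility: dict | None = None,
) -> pd.DataFrame:
    """Seventeen-year-like yearly price series per species x assortment.

    Prices follow a driftless multiplicative random walk with the
    configured per-assortment log-return volatility, so the volatility
    estimator downstream can be tested for parameter recovery.
    """
    levels = levels or DEFAULT_PRICE_LEVELS
    volatility = volatility or DEFAULT_PRICE_VOLATILITY
    rng = np.random.default_rng(seed)
    rows = []
    for sp in species:
        for a in assortments:
            p0 = levels[a] * rng.uniform(0.85, 1.15)
            sig = volatility[a]
            logret = rng.normal(0.0, sig, size=n_years - 1) if sig > 0 else np.zeros(n_years - 1)
            prices = p0 * np.exp(np.concatenate([[0.0], np.cumsum(logret)]))
            for yr, p in enumerate(prices):
                rows.append(
                    {
                        "species": sp,
                        "assortment_class": a,
                        "year": 2000 + yr,
                        "price": float(p),
                    }
                )
    return pd.DataFrame(rows)


def generate_wind_series(seed: int = 0, mu: float = 28.0, s: float = 4.0, n_years: int = 48) -> np.ndarray:
    """Yearly-maximum wind speeds (m/s) drawn from a Gumbel(mu, s)."""
    rng = np.random.default_rng(seed)
    x = mu + s * (-np.log(-np.log(rng.random(n_years))))
    return np.maximum(x, 0.1)


# ---------------------------------------------------------------------------
# GeoJSON / CSV interchange


def landscape_to_geojson(landscape: Landscape) -> dict:
    features = []
    for s in landscape.stands:
        features.append(
            {
                "type": "Feature",
                "geometry": shapely.geometry.mapping(s.polygon),
                "properties": {
                    "id": s.id,
                    "area_ha": s.area,
                    "species": s.dominant_species,
                    "age": s.age,
                    "existing_reserve": s.existing_reserve,
                    "topex_class": s.topex_class,
                },
            }
        )
    return {"type": "FeatureCollection", "features": features}


def landscape_from_geojson(obj: dict) -> Landscape:
    stands = []
    for f in obj["features"]:
        poly = shapely.geometry.shape(f["geometry"])
        pr = f["properties"]
        c = poly.centroid
        stands.append(
            Stand(
                id=int(pr["id"]),
                area=float(pr["area_ha"]),
                centroid=(float(c.x), float(c.y)),
                polygon=poly,
                dominant_species=str(pr["species"]),
                age=float(pr["age"]),
                existing_reserve=bool(pr["existing_reserve"]),
                topex_class=int(pr["topex_class"]),
            )
        )
    xs = [s.polygon.bounds for s in stands]
    bounds = (
        min(b[0] for b in xs),
        min(b[1] for b in xs),
        max(b[2] for b in xs),
        max(b[3] for b in xs),
    )
    return Landscape(stands=stands, bounds=bounds)
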