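"""Synthetic badger-tracking generator with ground truth.

Emulates the sampling process the excursion analysis assumes: a contiguous
Voronoi mosaic of ~10 social-group territories, four GPS fixes per night
at 22:00, 23:00, 01:00 and 02:00, seasonal activity with winter lethargy
in December-January, per-night excursion probabilities varying with sex,
age cohort and month, log-normal excursion depths beyond the home
boundary, isotropic GPS error (sd 7.5 m, so errors run "up to" ~15 m at
two standard deviations), and permanent collar failure.

Movement within the territory is a discrete-time mean-reverting walk
anchored at the home sett, with its step scale tied to the sett-to-boundary
distance and proposals clamped so that non-excursion fixes stay at least
30 m inside the home boundary before noise: under 7.5 m GPS error a
false-positive excursion (> 15 m outside) then requires a > 45 m noise
shift, a ~6-sigma event. On an excursion night exactly one scheduled fix
is displaced into a neighbouring territory at the drawn depth, mirroring
the one-retained-fix-per-night reduction and making ground truth and
detection comparable night for night.

Every stochastic choice flows from a single seed; identical configs and
seeds give identical outputs.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from datetime import date, timedelta

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import MultiPoint, Point, Polygon, box
from shapely.geometry.polygon import orient
from shapely.ops import voronoi_diagram

from .detection import age_cohort
from .geometry import TerritoryMap, TerritoryPolygon

logger = logging.getLogger(__name__)

FIX_HOURS = (22, 23, 1, 2)

# Per-night excursion probability defaults: higher April-September, a
# December-January trough (winter lethargy), young adults most mobile,
# males more active than females outside summer, and a November peak for
# breeding females (the late-autumn mating window).
_BASE_MONTH_PROB = {1: 0.03, 2: 0.06, 3: 0.06, 4: 0.13, 5: 0.13, 6: 0.13,
                    7: 0.13, 8: 0.13, 9: 0.13, 10: 0.06, 11: 0.06, 12: 0.03}
_COHORT_FACTOR = {"Juvenile": 0.6, "YoungAdult": 1.3, "OlderAdult": 1.0}

# Excursion depth beyond the home boundary: log-normal, shorter in the
# high-activity season (median 85 m Apr-Sep) and longer in the low season
# (median 180 m Oct-Mar).
_DEPTH_BY_SEASON = {"high": (math.log(85.0), 0.5), "low": (math.log(180.0), 0.5)}

# Probability a night is active (animal above ground with a working collar
# recording): reduced in the winter-lethargy months.
_ACTIVITY_BY_MONTH = {1: 0.5, 2: 0.75, 11: 0.75, 12: 0.5}
_ACTIVITY_DEFAULT = 0.9

# Within-territory ranging scale by month: summer home ranges approach the
# territory (which is why summer fixes delineate boundaries), winter ranges
# contract around the sett.
_RANGE_SCALE_BY_MONTH = {12: 0.4, 1: 0.4, 2: 0.6, 3: 0.6, 10: 0.6, 11: 0.6}
_RANGE_SCALE_DEFAULT = 1.0


def default_excursion_prob(sex: str, cohort: str, month: int,
                           breeding_status: str = "unknown") -> float:
    p = _BASE_MONTH_PROB[int(month)] * _COHORT_FACTOR.get(cohort, 1.0)
    if sex == "M" and not 4 <= int(month) <= 9:
        p *= 1.3
    if sex == "F" and breeding_status == "breeding" and int(month) == 11:
        p *= 2.0
    return min(p, 1.0)


def default_depth_params(month: int) -> tuple[float, float]:
    return _DEPTH_BY_SEASON["high" if 4 <= int(month) <= 9 else "low"]


@dataclass
class SimConfig:
    """Study conditions for one synthetic tracking campaign."""

    n_groups: int = 10
    study_region: tuple[float, float, float, float] = (0.0, 0.0, 5000.0, 5000.0)
    animals_per_group: int = 4
    start_date: date = date(2012, 1, 1)
    n_months: int = 12
    fix_hours: tuple[int, ...] = FIX_HOURS
    excursion_prob: float | dict | None = None   # None -> sex/age/month default table
    excursion_depth: tuple[float, float] | None = None  # (mu_log, sigma_log); None -> seasonal
    gps_noise_sd: float = 7.5
    activity: float | dict | None = None         # None -> winter-lethargy defaults
    collar_failure_rate: float = 0.002           # per-night hazard, permanent
    min_sett_spacing: float | None = None        # None -> 0.45 * sqrt(area / n)
    inner_margin_m: float = 30.0                 # non-excursion fixes stay this far inside
    # individual / social-group / year heterogeneity in excursion propensity
    # (log-odds sd) and the structural-zero mass: the probability that a
    # badger-month is an excursion-free month outright, beyond what the
    # nightly probabilities predict (the monthly frequency data are
    # zero-inflated). All four apply only to the default behavioural table:
    # an explicitly supplied excursion_prob is honoured exactly, so
    # controlled experiments stay controlled.
    animal_effect_sd: float = 0.3
    group_effect_sd: float = 0.25
    year_effect_sd: float = 0.25
    structural_zero_prob: float = 0.15
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_groups < 2:
            raise ValueError("need at least 2 groups for a contiguous mosaic")
        x0, y0, x1, y1 = self.study_region
        if x1 <= x0 or y1 <= y0:
            raise ValueError("study region must have positive area")
        if self.gps_noise_sd < 0 or not 0 <= self.collar_failure_rate < 1:
            raise ValueError("invalid noise or failure rate")

    @property
    def region(self) -> Polygon:
        return box(*self.study_region)

    def excursion_probability(self, sex: str, cohort: str, month: int,
                              breeding_status: str = "unknown") -> float:
        p = self.excursion_prob
        if p is None:
            return default_excursion_prob(sex, cohort, month, breeding_status)
        if isinstance(p, dict):
            return float(p[(sex, cohort, int(month))])
        return float(p)

    def depth_params(self, month: int) -> tuple[float, float]:
        if self.excursion_depth is None:
            return default_depth_params(month)
        mu, sigma = self.excursion_depth
        if sigma <= 0:
            raise ValueError("sigma_log must be positive")
        return float(mu), float(sigma)

    def activity_probability(self, month: int) -> float:
        a = self.activity
        if a is None:
            return _ACTIVITY_BY_MONTH.get(int(month), _ACTIVITY_DEFAULT)
        if isinstance(a, dict):
            return float(a[int(month)])
        return float(a)


@dataclass
class SimOutput:
    fixes: pd.DataFrame
    animals: pd.DataFrame
    truth: pd.DataFrame          # one row per active animal-night
    territory_map: TerritoryMap
    setts: dict[str, tuple[float, float]]
    config: SimConfig


def _sample_setts(config: SimConfig, rng: np.random.Generator) -> dict[str, tuple[float, float]]:
    x0, y0, x1, y1 = config.study_region
    area = (x1 - x0) * (y1 - y0)
    spacing = config.min_sett_spacing or 0.45 * math.sqrt(area / config.n_groups)
    # keep setts off the region edge so each cell has interior room
    margin = min(0.05 * min(x1 - x0, y1 - y0), spacing / 2)
    setts: list[tuple[float, float]] = []
    for _ in range(10_000):
        if len(setts) == config.n_groups:
            break
        pt = (rng.uniform(x0 + margin, x1 - margin), rng.uniform(y0 + margin, y1 - margin))
        if all(math.hypot(pt[0] - s[0], pt[1] - s[1]) >= spacing for s in setts):
            setts.append(pt)
    else:
        raise RuntimeError(
            f"could not place {config.n_groups} setts with spacing {spacing:.0f} m; "
            "shrink min_sett_spacing or enlarge the study region"
        )
    return {f"G{i + 1:02d}": s for i, s in enumerate(setts)}


def generate_territory_mosaic(
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> tuple[TerritoryMap, dict[str, tuple[float, float]]]:
    """Contiguous territory mosaic: Voronoi cells of the setts, clipped to the region."""
    rng = rng if rng is not None else np.random.default_rng(config.rng_seed)
    setts = _sample_setts(config, rng)
    region = config.region
    cells = voronoi_diagram(MultiPoint(list(setts.values())), envelope=region)
    year = config.start_date.year
    polygons: dict[str, TerritoryPolygon] = {}
    for gid, sett in setts.items():
        cell = next((c for c in cells.geoms if c.contains(Point(sett))), None)
        if cell is None:
            raise RuntimeError(f"no Voronoi cell contains sett of {gid}")
        clipped = orient(cell.intersection(region), sign=1.0)
        polygons[gid] = TerritoryPolygon(group_id=gid, year=year,
                                         polygon=clipped, source="voronoi")
    return TerritoryMap(year=year, polygons=polygons), setts


def _roster(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Collared animals: balanced sexes, mixed ages, some breeding females."""
    start_year = config.start_date.year
    rows = []
    template = [("M", 1), ("F", 2), ("M", 4), ("F", 6), ("F", 0), ("M", 3)]
    for g in range(config.n_groups):
        gid = f"G{g + 1:02d}"
        for a in range(config.animals_per_group):
            sex, age = template[(g + a) % len(template)]
            breeding = "unknown"
            if sex == "F":
                breeding = "breeding" if age >= 2 and (g + a) % 2 == 0 else "non_breeding"
            rows.append({
                "animal_id": f"{gid}A{a + 1}",
                "group_id": gid,
                "sex": sex,
                "birth_year": start_year - age,
                "breeding_status": breeding,
            })
    return pd.DataFrame(rows)


def _night_dates(config: SimConfig) -> list[date]:
    start = config.start_date
    end_month = start.month - 1 + config.n_months
    end_year = start.year + end_month // 12
    end = date(end_year, end_month % 12 + 1, 1)
    nights, d = [], start
    while d < end:
        nights.append(d)
        d += timedelta(days=1)
    return nights


def _excursion_target(
    home: Polygon,
    others: list[tuple[str, Polygon]],
    depth: float,
    rng: np.random.Generator,
    region_inner: Polygon | None = None,
    max_tries: int = 50,
) -> tuple[float, float, float, str]:
    """A point beyond the home boundary at ~`depth` m, inside a neighbour cell.

    Candidates step outward along the outward normal of a random boundary
    edge point (the home ring is CCW-oriented, so the outward normal of an
    edge (p1 -> p2) is (dy, -dx) normalised); the achieved distance beyond
    the boundary — equal to `depth` except near corners — is recorded as
    truth. If the drawn depth never lands inside a neighbour (cell too
    shallow there), the depth is halved: a bounded clamp the caller logs.
    """
    coords = np.asarray(home.exterior.coords)
    seg = np.diff(coords, axis=0)
    seg_len = np.hypot(seg[:, 0], seg[:, 1])
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    total = cum[-1]
    d = depth
    for attempt in range(max_tries):
        t = rng.uniform(0, total)
        i = int(np.searchsorted(cum, t, side="right") - 1)
        i = min(i, len(seg) - 1)
        frac = (t - cum[i]) / seg_len[i] if seg_len[i] > 0 else 0.0
        bx, by = coords[i] + frac * seg[i]
        nx, ny = seg[i, 1] / seg_len[i], -seg[i, 0] / seg_len[i]  # outward for CCW ring
        q = (bx + d * nx, by + d * ny)
        qp = Point(q)
        if region_inner is not None and not region_inner.covers(qp):
            continue  # keep targets well inside the study region
        for gid, poly in others:
            if poly.covers(qp):
                achieved = qp.distance(home)
                if achieved > 0:
                    return q[0], q[1], achieved, gid
        if attempt >= max_tries // 2:
            d = max(d / 2, 1.0)
    raise RuntimeError("could not place an excursion target in a neighbouring territory")


def simulate_tracks(
    config: SimConfig,
    territory_map: TerritoryMap,
    setts: dict[str, tuple[float, float]],
    rng: np.random.Generator | None = None,
) -> SimOutput:
    """Simulate all collared animals over the configured span."""
    rng = rng if rng is not None else np.random.default_rng(config.rng_seed)
    animals = _roster(config, rng)
    nights = _night_dates(config)
    region = config.region

    geoms = {gid: territory_map[gid].polygon for gid in territory_map.groups()}
    inner = {}
    for gid, poly in geoms.items():
        shrunk = poly.intersection(region).buffer(-config.inner_margin_m)
        if shrunk.is_empty:
            raise RuntimeError(f"territory {gid} too small for a {config.inner_margin_m} m inner margin")
        inner[gid] = shrunk
    shapely.prepare(list(inner.values()))

    phi = 0.6
    # excursion targets stay 6 noise-sd inside the region so noisy fixes
    # remain on the territory mosaic
    region_inner = region.buffer(-6 * config.gps_noise_sd) if config.gps_noise_sd else region
    if region_inner.is_empty:
        region_inner = region

    # latent excursion-propensity intercepts (log-odds); only modulate the
    # default behavioural table
    u_animal = {a: rng.normal(0, config.animal_effect_sd) for a in animals["animal_id"]}
    u_group = {g: rng.normal(0, config.group_effect_sd) for g in territory_map.groups()}
    years = sorted({n.year for n in nights})
    u_year = {y: rng.normal(0, config.year_effect_sd) for y in years}

    fix_rows, truth_rows = [], []
    clamped = 0
    for animal in animals.itertuples(index=False):
        home = geoms[animal.group_id]
        others = [(g, p) for g, p in geoms.items() if g != animal.group_id]
        sett = np.asarray(setts[animal.group_id])
        # ranging scale tied to the territory's effective radius so summer
        # fixes spread across the whole cell
        r_eff = math.sqrt(home.area / math.pi)
        inner_home = inner[animal.group_id]
        pos = sett.copy()
        alive = True
        u_het = u_animal[animal.animal_id] + u_group[animal.group_id]
        month_key = None
        zero_month = False
        for night in nights:
            if not alive:
                break
            month = night.month
            if config.excursion_prob is None and (night.year, month) != month_key:
                month_key = (night.year, month)
                zero_month = rng.random() < config.structural_zero_prob
            age = night.year - animal.birth_year
            cohort = age_cohort(max(age, 0))
            range_scale = _RANGE_SCALE_BY_MONTH.get(month, _RANGE_SCALE_DEFAULT)
            stationary_sd = 0.5 * r_eff * range_scale
            step_sd = max(stationary_sd * math.sqrt(1 - phi * phi), 5.0)
            if rng.random() >= config.activity_probability(month):
                # inactive night: no fixes recorded; collar hazard still runs
                alive = rng.random() >= config.collar_failure_rate
                continue
            p_exc = config.excursion_probability(animal.sex, cohort, month,
                                                 animal.breeding_status)
            if config.excursion_prob is None:
                if zero_month:
                    p_exc = 0.0
                else:
                    logit = math.log(p_exc / (1 - p_exc)) + u_het + u_year[night.year]
                    p_exc = 1 / (1 + math.exp(-logit))
            is_excursion = rng.random() < p_exc
            exc_idx = int(rng.integers(len(config.fix_hours))) if is_excursion else -1

            target = None
            if is_excursion:
                mu, sigma = config.depth_params(month)
                depth = float(rng.lognormal(mu, sigma))
                qx, qy, achieved, target_gid = _excursion_target(
                    home, others, depth, rng, region_inner)
                if achieved < depth * 0.99:
                    clamped += 1
                target = (qx, qy, achieved, target_gid)

            night_positions = []
            for i in range(len(config.fix_hours)):
                if i == exc_idx:
                    night_positions.append((target[0], target[1]))
                    continue
                for _ in range(30):
                    prop = sett + phi * (pos - sett) + rng.normal(0, step_sd, 2)
                    if inner_home.covers(Point(prop)):
                        pos = prop
                        break
                else:
                    pos = sett + 0.5 * (pos - sett)  # pull home if proposals keep failing
                night_positions.append(tuple(pos))

            noise = rng.normal(0, config.gps_noise_sd, (len(night_positions), 2))
            for i, ((px, py), hour) in enumerate(zip(night_positions, config.fix_hours)):
                fix_day = night if hour >= 12 else night + timedelta(days=1)
                fix_rows.append({
                    "animal_id": animal.animal_id,
                    "group_id": animal.group_id,
                    "timestamp": pd.Timestamp(fix_day) + pd.Timedelta(hours=hour),
                    "x": px + noise[i, 0],
                    "y": py + noise[i, 1],
                })
            truth_rows.append({
                "animal_id": animal.animal_id,
                "night_date": night,
                "is_excursion_night": is_excursion,
                "true_target_group": target[3] if target else "",
                "true_depth_m": target[2] if target else 0.0,
            })
            alive = rng.random() >= config.collar_failure_rate
    if clamped:
        logger.warning("%d excursion depths clamped to fit inside a neighbouring cell", clamped)

    fixes = pd.DataFrame(fix_rows).sort_values(["animal_id", "timestamp"]).reset_index(drop=True)
    truth = pd.DataFrame(truth_rows)
    return SimOutput(fixes=fixes, animals=animals, truth=truth,
                     territory_map=territory_map, setts=setts, config=config)


def simulate(config: SimConfig) -> SimOutput:
    """Mosaic + tracks from a single seed."""
    rng = np.random.default_rng(config.rng_seed)
    mosaic, setts = generate_territory_mosaic(config, rng)
    return simulate_tracks(config, mosaic, setts, rng)


def write_dataset(sim: SimOutput, out_dir) -> dict[str, str]:
    """Write the exact file dialects the pipeline reads, plus ground truth.

    truth.csv is for validation only and is never read by the pipeline.
    Returns the paths written, keyed by role.
    """
    from dataclasses import asdict, replace
    from pathlib import Path

    import yaml

    from . import io as fio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "fixes": out / "fixes.csv",
        "animals": out / "animals.csv",
        "truth": out / "truth.csv",
        "territories": out / "territories.geojson",
        "config": out / "simconfig.yaml",
    }
    fixes = sim.fixes.copy()
    fixes["timestamp"] = fixes["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%S")
    fio.write_table(fixes, paths["fixes"])
    fio.write_table(sim.animals, paths["animals"])
    fio.write_table(sim.truth, paths["truth"])
    # territories are constant over the campaign: emit one copy per night-year
    years = sorted(pd.to_datetime(sim.truth["night_date"]).dt.year.unique())
    maps = {
        int(yr): TerritoryMap(year=int(yr), polygons={
            g: replace(sim.territory_map[g], year=int(yr))
            for g in sim.territory_map.groups()})
        for yr in years
    }
    fio.write_territories(maps, paths["territories"])
    cfg = asdict(sim.config)
    cfg["start_date"] = sim.config.start_date.isoformat()
    cfg["setts"] = {g: [float(x), float(y)] for g, (x, y) in sim.setts.items()}
    paths["config"].write_text(yaml.safe_dump(cfg, sort_keys=True))
    return {k: str(v) for k, v in paths.items()}
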