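"""Seeded synthetic landscapes and travel surveys.

Restricted national data (postal-code GIS layers, travel-survey microdata)
cannot ship with a toolkit, so every downstream stage is exercised on a
synthetic world with a *known* data-generating process:

* a planar landscape on a square-cell grid — population as a sum of
  radially decaying urban-gradient kernels, land-use classes drawn with
  urbanicity-dependent probabilities, a jittered grid road network,
  transit stops from an inhomogeneous Poisson process whose intensity
  rises with population, and a sidewalk share increasing with population
  (so population and sidewalk density are positively dependent by
  construction);
* a one-day travel survey whose walking-minutes outcome follows a latent
  linear model left-censored at zero,
  ``y* = intercept + beta * walkability + gamma' covariates + eps``,
  ``y = max(0, y*)`` reported in whole diary minutes, with the intercept
  calibrated by bisection so a configured share of respondents (default
  55%, emulating the more-than-half-report-no-walking regime) is censored.

Everything is driven by one scenario seed expanded into per-stage
substreams, so landscape and survey can be regenerated independently and
bit-identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from shapely.geometry import LineString, box

from . import survey as survey_mod
from .components import LANDUSE_CLASSES, LandscapeBundle
from .grids import GridLayer

#: distinct substreams of the scenario seed
_STREAM_LANDSCAPE = 11
_STREAM_SURVEY = 23

DEFAULT_COVARIATE_MARGINS: dict[str, dict[str, float]] = {
    "sex": {"female": 0.525, "male": 0.475},
    "age_group": {"18_35": 0.324, "36_49": 0.308, "50_65": 0.368},
    "ethnicity": {"native_dutch": 0.83, "other_western": 0.084,
                  "non_western": 0.086},
    "education": {"low": 0.032, "medium": 0.564, "high": 0.404},
    "work_status": {"part_time": 0.213, "full_time": 0.548,
                    "student": 0.078, "not_working": 0.161},
    "income": {"low": 0.179, "medium": 0.314, "high": 0.507},
    "car_ownership": {"no_car": 0.118, "one_car": 0.454, "two_plus": 0.428},
    "household": {"single": 0.162, "couple": 0.264, "couple_children": 0.486,
                  "single_parent": 0.068, "other": 0.020},
    "season": {"spring": 0.26, "summer": 0.284, "autumn": 0.224,
               "winter": 0.232},
    "weekday": {"weekday": 0.742, "weekend": 0.258},
    "response_type": {"internet": 0.380, "telephone": 0.331,
                      "face_to_face": 0.289},
    "cycled_same_day": {"no": 0.745, "yes": 0.255},
}

#: latent-outcome shifts (minutes) by covariate level; continuous
#: covariates map to a slope
DEFAULT_COVARIATE_EFFECTS: dict[str, dict[str, float] | float] = {
    "cycled_same_day": {"yes": 4.0},
    "weekday": {"weekend": 3.0},
    "sex": {"male": -1.5},
    "ses": 0.5,
}

TRIP_PURPOSES = tuple(survey_mod.DEFAULT_PURPOSE_MAP)
_PURPOSE_WEIGHTS = (0.14, 0.05, 0.15, 0.10, 0.28, 0.08, 0.10, 0.07, 0.03)


@dataclass(frozen=True)
class SyntheticScenario:
    """Fully reproducible configuration of one synthetic test world."""

    seed: int = 1
    extent_m: float = 5000.0
    cell_m: float = 25.0
    n_centres: int = 3
    n_units: int = 400
    n_respondents: int = 2000
    #: latent minutes per point of the 0-100 walkability index
    true_beta_walkability: float = 0.85
    #: latent minutes per unit of a component z-score, keyed by component
    #: name (used to build worlds where one component drives the outcome)
    true_component_betas: dict = field(default_factory=dict)
    true_covariate_effects: dict = field(
        default_factory=lambda: dict(DEFAULT_COVARIATE_EFFECTS))
    #: latent noise SD in minutes
    sigma: float = 35.0
    #: latent intercept (minutes); None = calibrate to ``zero_target``
    intercept: float | None = None
    #: target share of zero (censored) outcomes for the calibration
    zero_target: float = 0.55
    #: relative landscape noise scale (0 = deterministic surfaces)
    noise: float = 1.0
    #: peak population per cell at an urban centre
    pop_peak: float = 5.0
    road_spacing_m: float = 250.0
    highway_prob: float = 0.08
    n_neighbourhood_rows: int = 5
    abroad_rate: float = 0.01
    immobile_rate: float = 0.015
    covariate_margins: dict = field(
        default_factory=lambda: {k: dict(v) for k, v in
                                 DEFAULT_COVARIATE_MARGINS.items()})

    def __post_init__(self) -> None:
        if self.extent_m <= 0 or self.cell_m <= 0:
            raise ValueError("extent_m and cell_m must be positive")
        n_side = self.extent_m / self.cell_m
        if abs(n_side - round(n_side)) > 1e-9:
            raise ValueError("extent_m must be divisible by cell_m")
        n_cells = int(round(n_side)) ** 2
        if self.n_units > n_cells:
            raise ValueError(f"n_units = {self.n_units} exceeds cell count {n_cells}")
        if self.n_units < 1 or self.n_respondents < 1:
            raise ValueError("n_units and n_respondents must be positive")
        if not 0 < self.zero_target < 1:
            raise ValueError("zero_target must be in (0, 1)")

    def with_(self, **kw) -> "SyntheticScenario":
        return replace(self, **kw)


def _rng(scenario: SyntheticScenario, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([scenario.seed, stream]))


# -- landscape ------------------------------------------------------------

def generate_landscape(scenario: SyntheticScenario) -> LandscapeBundle:
    """Build all raw layers of one synthetic world (deterministic per seed)."""
    rng = _rng(scenario, _STREAM_LANDSCAPE)
    n = int(round(scenario.extent_m / scenario.cell_m))
    cell = scenario.cell_m
    template = GridLayer((0.0, 0.0), cell, np.zeros((n, n)))
    cx, cy = template.cell_centres()

    # population: radially decaying kernels around urban centres + noise
    pop = np.zeros((n, n))
    lo, hi = 0.1 * scenario.extent_m, 0.9 * scenario.extent_m
    centres = rng.uniform(lo, hi, size=(scenario.n_centres, 2))
    for k in range(scenario.n_centres):
        amp = scenario.pop_peak * rng.uniform(0.7, 1.3)
        sd = scenario.extent_m / 8.0 * rng.uniform(0.8, 1.2)
        d2 = (cx - centres[k, 0]) ** 2 + (cy - centres[k, 1]) ** 2
        pop += amp * np.exp(-d2 / (2.0 * sd * sd))
    pop += scenario.noise * 0.05 * scenario.pop_peak * rng.standard_normal((n, n))
    pop = np.maximum(pop, 0.0)
    pop_layer = template.like(pop, "count")

    # urbanicity in [0, 1] drives land use, transit and sidewalks
    u = pop / pop.max() if pop.max() > 0 else np.zeros_like(pop)

    # land use: categorical draw per cell; at u = 0 only residential fill
    # and non-relevant "other" area remain
    probs = np.stack([
        0.12 * u,                # commercial
        0.08 * u,                # socio_cultural
        0.25 + 0.15 * u,         # residential
        0.08 * u,                # offices_public
        0.15 * u,                # green_recreation
    ])
    other = 1.0 - probs.sum(axis=0)
    cum = np.cumsum(np.concatenate([other[None], probs]), axis=0)
    draw = rng.random((n, n))
    codes = (draw[None] >= cum).sum(axis=0)   # 0 = other, 1.. = LANDUSE_CLASSES
    landuse = template.like(codes.astype(int), "category")

    # sidewalk share increases with population density; the noise needs a
    # spatially coherent part, otherwise buffer averaging removes it and
    # sidewalk density becomes collinear with population density
    coarse = _coarse_field(rng, n, block=8)
    sw = (0.05 + 0.5 * u + scenario.noise * (0.15 * coarse
                                             + 0.03 * rng.standard_normal((n, n))))
    sidewalk = template.like(np.clip(sw, 0.0, 1.0), "fraction")

    roads = _grid_roads(scenario, rng)
    transit = _transit_points(scenario, rng, template, u)
    centroids = _unit_centroids(scenario, rng, template, pop)
    neighbourhoods = _neighbourhood_grid(scenario)

    return LandscapeBundle(
        population=pop_layer, landuse=landuse, sidewalk=sidewalk,
        roads=roads, transit_points=transit, centroids=centroids,
        neighbourhoods=neighbourhoods,
        landuse_codes=("other",) + LANDUSE_CLASSES,
    )


def _coarse_field(rng, n: int, block: int) -> np.ndarray:
    """Blockwise-constant standard-normal field (spatially autocorrelated)."""
    k = max(-(-n // block), 1)      # ceil division covers the full grid
    coarse = rng.standard_normal((k, k))
    up = np.kron(coarse, np.ones((block, block)))
    return up[:n, :n]


def _grid_roads(scenario, rng):
    """Jittered axis-aligned street grid, noded at every crossing."""
    ext = scenario.extent_m
    spacing = scenario.road_spacing_m
    k = int(ext // spacing)
    jit = scenario.noise * 0.2 * spacing
    xs = np.sort(np.clip(spacing * (np.arange(1, k) )
                         + rng.uniform(-jit, jit, k - 1), 1.0, ext - 1.0))
    ys = np.sort(np.clip(spacing * (np.arange(1, k))
                         + rng.uniform(-jit, jit, k - 1), 1.0, ext - 1.0))
    v_class = np.where(rng.random(len(xs)) < scenario.highway_prob,
                       "highway", "street")
    h_class = np.where(rng.random(len(ys)) < scenario.highway_prob,
                       "highway", "street")
    roads = []
    for x, cls in zip(xs, v_class):
        knots = [0.0, *ys, ext]
        for a, b in zip(knots[:-1], knots[1:]):
            roads.append((LineString([(x, a), (x, b)]), str(cls)))
    for y, cls in zip(ys, h_class):
        knots = [0.0, *xs, ext]
        for a, b in zip(knots[:-1], knots[1:]):
            roads.append((LineString([(a, y), (b, y)]), str(cls)))
    return roads


def _transit_points(scenario, rng, template, u):
    """Inhomogeneous Poisson stops (intensity rising with urbanicity)."""
    lam = 0.001 + 0.05 * u
    counts = rng.poisson(lam)
    rows, cols = np.nonzero(counts)
    pts = []
    cell = template.cell_m
    for r, c, m in zip(rows, cols, counts[rows, cols]):
        xy = rng.uniform(0.0, cell, size=(m, 2))
        xy[:, 0] += c * cell
        xy[:, 1] += r * cell
        pts.append(xy)
    return (np.vstack(pts) if pts else np.empty((0, 2)))


def _unit_centroids(scenario, rng, template, pop):
    """Postal-code centroids: population-weighted distinct cells, jittered."""
    n = template.nrows
    w = (pop + 1e-3).ravel()
    idx = rng.choice(n * n, size=scenario.n_units, replace=False, p=w / w.sum())
    rows, cols = np.divmod(idx, n)
    cell = template.cell_m
    x = (cols + rng.uniform(0.1, 0.9, scenario.n_units)) * cell
    y = (rows + rng.uniform(0.1, 0.9, scenario.n_units)) * cell
    return pd.DataFrame({
        "unit_id": [f"U{k:04d}" for k in range(scenario.n_units)],
        "x": x, "y": y,
    })


def _neighbourhood_grid(scenario):
    """Rectangular administrative-neighbourhood partition of the extent."""
    k = scenario.n_neighbourhood_rows
    step = scenario.extent_m / k
    zones = []
    for i in range(k):
        for j in range(k):
            zones.append((f"N{i:02d}{j:02d}",
                          box(j * step, i * step, (j + 1) * step, (i + 1) * step)))
    return zones


# -- survey ---------------------------------------------------------------

def calibrate_intercept(linear_part: np.ndarray, sigma: float,
                        zero_target: float) -> float:
    """Intercept making the expected zero share equal ``zero_target``.

    The expected censored share at intercept ``c`` is the mean over
    respondents of ``Phi(-(c + linear)/sigma)``, monotone decreasing in
    ``c``; solved by bisection.  With ``sigma = 0`` the share is the step
    function ``mean(c + linear <= 0)`` and the matching quantile is used.
    """
    from scipy.stats import norm

    lin = np.asarray(linear_part, dtype=float)
    if sigma == 0:
        return float(-np.quantile(lin, zero_target))
    lo, hi = -10.0 * sigma + lin.min(), 10.0 * sigma + lin.max()
    lo, hi = lo - abs(lo), hi + abs(hi) + 1.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        share = float(norm.cdf(-(mid + lin) / sigma).mean())
        if share > zero_target:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-9:
            break
    return 0.5 * (lo + hi)


def _covariate_shift(df: pd.DataFrame, effects: dict) -> np.ndarray:
    shift = np.zeros(len(df))
    for var, eff in effects.items():
        if isinstance(eff, dict):
            for level, delta in eff.items():
                shift += delta * (df[var].astype(str) == level).to_numpy()
        else:
            shift += eff * df[var].to_numpy(dtype=float)
    return shift


def generate_survey(scenario: SyntheticScenario,
                    units: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Synthesize ``(respondents, trips)`` on a finished index table.

    ``units`` must carry ``unit_id`` and a 0-100 ``walkability`` column
    (and, for component-driven worlds, the ``z_*`` columns).  Respondent
    covariates are drawn independently from configured margins; the
    observed outcome is the left-censored latent model; trips are
    synthesized so that purpose-classified minutes re-sum *exactly* to the
    daily total, with metres = minutes x a per-respondent walking speed
    near 80 m/min.
    """
    if len(units) == 0:
        raise ValueError("empty unit table")
    if "walkability" not in units.columns:
        raise ValueError("units must carry a finished 0-100 walkability index")
    rng = _rng(scenario, _STREAM_SURVEY)
    n = scenario.n_respondents
    uidx = rng.integers(0, len(units), size=n)

    df = pd.DataFrame({
        "respondent_id": [f"R{k:05d}" for k in range(n)],
        "unit_id": units["unit_id"].to_numpy()[uidx],
        "walkability": units["walkability"].to_numpy(dtype=float)[uidx],
    })
    for var, margins in scenario.covariate_margins.items():
        levels = list(margins)
        p = np.asarray([margins[l] for l in levels], dtype=float)
        df[var] = rng.choice(levels, size=n, p=p / p.sum())

    # age consistent with the drawn group, with a small out-of-range tail
    # so the exclusion rules have work to do
    lo = df["age_group"].map({"18_35": 18, "36_49": 36, "50_65": 50}).to_numpy()
    hi = df["age_group"].map({"18_35": 35, "36_49": 49, "50_65": 65}).to_numpy()
    age = rng.integers(lo, hi + 1)
    tail = rng.random(n) < 0.02
    age[tail] = rng.choice([16, 17, 66, 67, 70], size=int(tail.sum()))
    df["age"] = age

    # neighbourhood SES: unit-level, mildly *decreasing* in walkability
    walk_z = ((units["walkability"] - units["walkability"].mean())
              / units["walkability"].std(ddof=1)).to_numpy()
    ses_unit = -0.12 * walk_z + 1.1 * rng.standard_normal(len(units))
    df["ses"] = ses_unit[uidx]

    # urbanization degree from unit population density tertiles
    dens_col = ("population_density" if "population_density" in units.columns
                else "walkability")
    dens = units[dens_col].to_numpy(dtype=float)[uidx]
    q1, q2 = np.quantile(dens, [1 / 3, 2 / 3])
    df["urbanization"] = np.where(dens <= q1, "rural",
                                  np.where(dens <= q2, "urban", "highly_urban"))

    df["no_mobility_personal"] = rng.random(n) < scenario.immobile_rate
    df["travelled_abroad"] = rng.random(n) < scenario.abroad_rate

    # latent outcome
    lin = scenario.true_beta_walkability * df["walkability"].to_numpy()
    for comp, b in scenario.true_component_betas.items():
        zcol = f"z_{comp}"
        if zcol not in units.columns:
            raise ValueError(f"component-driven effect needs column {zcol!r} in units")
        lin = lin + b * units[zcol].to_numpy(dtype=float)[uidx]
    lin = lin + _covariate_shift(df, scenario.true_covariate_effects)
    intercept = (scenario.intercept if scenario.intercept is not None
                 else calibrate_intercept(lin, scenario.sigma, scenario.zero_target))
    eps = scenario.sigma * rng.standard_normal(n) if scenario.sigma > 0 else 0.0
    y_star = intercept + lin + eps
    # diaries report whole minutes; rounding keeps trip re-sums exact in
    # floating point under any summation order
    y = np.round(np.maximum(y_star, 0.0))
    df["intercept_used"] = intercept
    df["y_latent"] = y_star

    speed = np.clip(rng.normal(80.0, 4.0, size=n), 60.0, 100.0)
    df["walk_speed_m_min"] = speed
    trips = _synthesize_trips(rng, df, y, speed)
    respondents = survey_mod.derive_daily_outcomes(trips, df)
    return respondents, trips


def _synthesize_trips(rng, df, y, speed) -> pd.DataFrame:
    """Split each positive daily total into purpose-labelled trips.

    Whole minutes are allocated multinomially over the drawn trips and
    zero-minute draws dropped, so per-respondent minutes re-sum exactly to
    the daily total.
    """
    weights = np.asarray(_PURPOSE_WEIGHTS)
    rows = []
    for i in range(len(df)):
        if y[i] <= 0:
            continue
        n_trips = min(1 + int(rng.binomial(2, 0.45)), int(y[i]))
        purposes = rng.choice(TRIP_PURPOSES, size=n_trips,
                              p=weights / weights.sum())
        props = rng.dirichlet(np.ones(n_trips))
        minutes = rng.multinomial(int(y[i]), props).astype(float)
        keep = minutes > 0
        minutes, purposes = minutes[keep], purposes[keep]
        n_trips = len(minutes)
        for t in range(n_trips):
            rows.append({
                "respondent_id": df["respondent_id"].iat[i],
                "purpose": str(purposes[t]),
                "mode": "walk",
                "walk_minutes": float(minutes[t]),
                "walk_metres": float(minutes[t] * speed[i]),
                "season": df["season"].iat[i],
                "weekday": df["weekday"].iat[i],
            })
    return pd.DataFrame(rows, columns=["respondent_id", "purpose", "mode",
                                       "walk_minutes", "walk_metres",
                                       "season", "weekday"])
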