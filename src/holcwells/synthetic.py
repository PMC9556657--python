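"""Seeded synthetic cities with known counterfactual ground truth.

The generator emulates the confounding structure the real analysis must
overcome.  A city is an ``n_rows x n_cols`` grid of square neighborhoods
(side ``cell_km``).  A latent desirability field U — a spatially smooth Gaussian field (iid
normals convolved with a 3x3 kernel, rescaled to sd ``confounder_sd``) plus
a north–south linear trend whose span also scales with ``confounder_sd`` —
drives everything.  Smoothness at the tract scale matters: tract covariates
are built from tract-averaged U, so a rough field would leave neighborhood-
level confounding unobservable by construction and no estimator could
recover the ground truth.  The field drives:

* grades are a noisy quartile discretization of −U, so grade is confounded
  with U but not determined by it;
* census tracts are a second square grid shifted by ``tract_offset_frac``
  of a cell in both axes, so tracts straddle neighborhoods; tract
  covariates are linear in the area-weighted mean of U over the tract plus
  independent noise, with gradient signs as in the 1940 census (median home
  value and high-school completion fall A→D, Black/foreign-born/non-White
  proportions rise, radio ownership falls, ...);
* wells follow an inhomogeneous Poisson process with per-neighborhood
  log-intensity ``base_log_intensity + grade_log_step·grade_index − 0.5·U``
  (wells per km²) — undesirable land attracts wells as well as bad grades,
  so the naive grade contrast overstates the causal one; each well is dated before appraisal with probability
  ``frac_pre``, after otherwise, and loses all four dates with probability
  ``frac_undated``.

Ground truth records U, the expected count each neighborhood would have had
under every counterfactual grade, and the resulting true adjacent-pair
effects, enabling parameter-recovery tests of the estimation pipeline.

``simulate_matched_scenario`` is a companion arm-level generator with an
exactly additive, homogeneous designed effect (a Poisson intensity shift)
and confounding through one observed covariate, used for estimator
calibration studies where the target effect must be known in closed form.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Point, Polygon

from .types import GRADES, Grade, Neighborhood, WellRecord, COVARIATE_NAMES

__all__ = [
    "CityConfig",
    "GroundTruth",
    "SyntheticStudy",
    "generate_study",
    "true_ate",
    "simulate_matched_scenario",
]

#: standard deviation of the noise added to −U before quartile grading
GRADE_NOISE_SD = 0.5

#: geometric-lag success probability for well year offsets from appraisal
YEAR_LAG_P = 0.25

#: marginal well-type mix (oil, gas, oil_and_gas, injection, unknown)
WELL_TYPE_PROBS = (0.35, 0.25, 0.18, 0.02, 0.20)


@dataclass(frozen=True)
class CityConfig:
    """Parameters of one synthetic city (defaults: a mid-size oil town)."""

    n_rows: int = 10
    n_cols: int = 10
    cell_km: float = 1.0
    tract_offset_frac: float = 0.35
    appraisal_year: int = 1937
    base_log_intensity: float = float(np.log(2.0))  # log wells/km² for grade A
    grade_log_step: float = float(np.log(1.3))
    confounder_sd: float = 0.8
    frac_undated: float = 0.3
    frac_pre: float = 0.5
    seed: int = 0
    city: str = "synthcity"
    perturb: float = 0.0  # grid-node jitter as a fraction of cell side
    trend: float = 1.0  # north–south trend span, in units of confounder_sd
    origin: tuple[float, float] = (0.0, 0.0)  # south-west corner, meters

    def __post_init__(self) -> None:
        if self.n_rows <= 0 or self.n_cols <= 0 or self.n_rows * self.n_cols < 8:
            raise ValueError("grid must be positive with n_rows*n_cols >= 8")
        if self.cell_km <= 0:
            raise ValueError("cell_km must be positive")
        for name in ("tract_offset_frac", "frac_undated", "frac_pre"):
            v = getattr(self, name)
            if not (0 <= v <= 1) or (name == "tract_offset_frac" and v >= 1):
                raise ValueError(f"{name} must lie in [0, 1)")
        if not (0 <= self.perturb < 0.5):
            raise ValueError("perturb must lie in [0, 0.5)")


@dataclass
class GroundTruth:
    """Counterfactual bookkeeping for one synthetic city."""

    latent_confounder: pd.Series  # U per neighborhood id
    grades: pd.Series  # realized grade per neighborhood id
    expected_count_by_grade: pd.DataFrame  # index nbhd id, columns A..D
    retention: dict[str, float]  # period → date-retention fraction

    def to_jsonable(self) -> dict:
        return {
            "latent_confounder": self.latent_confounder.to_dict(),
            "grades": self.grades.to_dict(),
            "expected_count_by_grade": self.expected_count_by_grade.to_dict(),
            "retention": self.retention,
        }

    @classmethod
    def from_jsonable(cls, obj: dict) -> "GroundTruth":
        return cls(
            latent_confounder=pd.Series(obj["latent_confounder"], dtype=float),
            grades=pd.Series(obj["grades"]),
            expected_count_by_grade=pd.DataFrame(obj["expected_count_by_grade"]),
            retention={k: float(v) for k, v in obj["retention"].items()},
        )


@dataclass
class SyntheticStudy:
    """One generated city: geometry, attributes, wells, ground truth."""

    neighborhoods: list[Neighborhood]
    tracts: list[tuple[str, Polygon]]
    tract_attributes: pd.DataFrame
    wells: list[WellRecord]
    truth: GroundTruth
    config: CityConfig = field(default=None)


def _grid_nodes(n_rows: int, n_cols: int, s: float, perturb: float, rng) -> np.ndarray:
    """(n_rows+1, n_cols+1, 2) node coordinates; interior nodes jittered."""
    xs = np.arange(n_cols + 1) * s
    ys = np.arange(n_rows + 1) * s
    nodes = np.stack(np.meshgrid(xs, ys), axis=-1)  # (rows+1, cols+1, 2)
    if perturb > 0:
        jit = rng.uniform(-perturb * s, perturb * s, size=nodes.shape)
        jit[0, :, :] = 0.0
        jit[-1, :, :] = 0.0
        jit[:, 0, :] = 0.0
        jit[:, -1, :] = 0.0
        nodes = nodes + jit
    return nodes


def _cell_polygon(nodes: np.ndarray, r: int, c: int) -> Polygon:
    return Polygon([
        tuple(nodes[r, c]), tuple(nodes[r, c + 1]),
        tuple(nodes[r + 1, c + 1]), tuple(nodes[r + 1, c]),
    ])


def _sample_in_polygon(poly: Polygon, n: int, rng) -> np.ndarray:
    """Uniform points in a polygon by bounding-box rejection."""
    if n == 0:
        return np.empty((0, 2))
    minx, miny, maxx, maxy = poly.bounds
    out: list[np.ndarray] = []
    need = n
    while need > 0:
        m = max(32, 2 * need)
        pts = np.column_stack([
            rng.uniform(minx, maxx, m), rng.uniform(miny, maxy, m),
        ])
        inside = shapely.contains_xy(poly, pts[:, 0], pts[:, 1])
        hit = pts[inside][:need]
        out.append(hit)
        need -= len(hit)
    return np.vstack(out)


# covariate model: value = intercept + slope·(−Ū_tract) + N(0, sd), clipped.
# Gradient signs follow the observed A→D census gradients.
_COV_MODEL: dict[str, tuple[float, float, float, float, float]] = {
    # name: (intercept, slope on −Ū, noise sd, clip lo, clip hi)
    "total_population": (3000.0, 800.0, 300.0, 0.0, np.inf),
    "prop_black": (0.08, 0.10, 0.03, 0.0, 1.0),
    "prop_foreign_born": (0.18, 0.05, 0.03, 0.0, 1.0),
    "prop_nonwhite_employed": (0.10, 0.08, 0.03, 0.0, 1.0),
    "prop_hs_complete": (0.15, -0.06, 0.02, 0.0, 1.0),
    "n_homes": (900.0, 200.0, 100.0, 0.0, np.inf),
    "median_home_value": (5000.0, -1500.0, 400.0, 200.0, np.inf),
    "prop_major_repair": (0.10, 0.06, 0.02, 0.0, 1.0),
    "prop_radio": (0.94, -0.03, 0.01, 0.0, 1.0),
    "people_per_home": (3.2, -0.12, 0.15, 0.5, np.inf),
}
assert tuple(_COV_MODEL) == COVARIATE_NAMES


def generate_study(config: CityConfig) -> SyntheticStudy:
    """Generate one synthetic city, deterministically from ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    s = config.cell_km * 1000.0
    nr, nc = config.n_rows, config.n_cols

    nodes = _grid_nodes(nr, nc, s, config.perturb, rng)
    nodes = nodes + np.asarray(config.origin, dtype=float)
    polys: list[Polygon] = []
    ids: list[str] = []
    rows_frac = np.empty(nr * nc)
    k = 0
    for r in range(nr):
        for c in range(nc):
            polys.append(_cell_polygon(nodes, r, c))
            ids.append(f"{config.city}-{r:02d}{c:02d}")
            rows_frac[k] = (r + 0.5) / nr
            k += 1
    n = len(polys)

    # latent desirability: smooth field + north–south trend, both scaled by
    # confounder_sd so confounder_sd = 0 switches confounding off entirely
    z = rng.normal(0.0, 1.0, (nr, nc))
    kern = np.array([[1.0, 2.0, 1.0], [2.0, 4.0, 2.0], [1.0, 2.0, 1.0]])
    zp = np.pad(z, 1, mode="edge")
    smooth = sum(
        kern[di, dj] * zp[di:di + nr, dj:dj + nc]
        for di in range(3)
        for dj in range(3)
    ) / kern.sum()
    # kernel-averaged iid noise has sd sqrt(Σk²)/Σk; rescale to unit sd
    smooth = smooth * kern.sum() / np.sqrt((kern ** 2).sum())
    trend = config.trend * config.confounder_sd * (rows_frac - 0.5)
    U = config.confounder_sd * smooth.ravel() + trend

    # noisy quartile grading of -U: exact quarters by rank
    z = -U + rng.normal(0.0, GRADE_NOISE_SD, n)
    order = np.argsort(z, kind="stable")
    grade_idx = np.empty(n, dtype=int)
    grade_idx[order] = (np.arange(n) * 4) // n
    grades = [GRADES[i] for i in grade_idx]

    neighborhoods = [
        Neighborhood(ids[i], config.city, grades[i], polys[i], config.appraisal_year)
        for i in range(n)
    ]

    # tract grid shifted by tract_offset_frac of a cell in both axes
    ox, oy = config.origin
    off = config.tract_offset_frac * s
    txs = np.arange(-1, nc + 1) * s + off + ox
    tys = np.arange(-1, nr + 1) * s + off + oy
    city_hull = shapely.box(ox, oy, ox + nc * s, oy + nr * s)
    tracts: list[tuple[str, Polygon]] = []
    for i in range(len(tys) - 1):
        for j in range(len(txs) - 1):
            g = shapely.box(txs[j], tys[i], txs[j + 1], tys[i + 1])
            if g.intersection(city_hull).area > 0:
                tracts.append((f"{config.city}-t{i:02d}{j:02d}", g))

    # area-weighted mean U over each tract (over its overlap with the city)
    areas = np.array([p.area for p in polys])
    u_bar = np.empty(len(tracts))
    for t, (_, tg) in enumerate(tracts):
        w = np.array([tg.intersection(p).area for p in polys])
        u_bar[t] = (w @ U) / w.sum() if w.sum() > 0 else 0.0

    attrs = {}
    for name, (b0, b1, sd, lo, hi) in _COV_MODEL.items():
        attrs[name] = np.clip(b0 + b1 * (-u_bar) + rng.normal(0, sd, len(tracts)), lo, hi)
    tract_attributes = pd.DataFrame(attrs, index=[tid for tid, _ in tracts])
    tract_attributes.index.name = "tract_id"

    # wells: per-neighborhood Poisson with log-intensity in wells/km²
    area_km2 = areas / 1e6
    log_lambda = (
        config.base_log_intensity
        + config.grade_log_step * grade_idx
        - 0.5 * U
    )
    expected = np.exp(log_lambda) * area_km2
    counts = rng.poisson(expected)

    wells: list[WellRecord] = []
    wid = 0
    type_probs = np.asarray(WELL_TYPE_PROBS)
    type_names = ("oil", "gas", "oil_and_gas", "injection", "unknown")
    for i in range(n):
        pts = _sample_in_polygon(polys[i], int(counts[i]), rng)
        for x, y in pts:
            is_pre = rng.random() < config.frac_pre
            lag = int(rng.geometric(YEAR_LAG_P)) - 1
            year = (
                config.appraisal_year - 1 - lag
                if is_pre
                else config.appraisal_year + 1 + lag
            )
            undated = rng.random() < config.frac_undated
            ti = int(rng.choice(5, p=type_probs))
            yearval = None if undated else year
            wells.append(WellRecord(
                id=f"{config.city}-w{wid:05d}",
                location=Point(float(x), float(y)),
                well_type=type_names[ti],
                spud_year=yearval,
                completion_year=yearval,
                first_prod_year=yearval,
                last_prod_year=yearval,
            ))
            wid += 1

    # counterfactual expected counts under every grade
    ecg = pd.DataFrame(
        {
            g.value: np.exp(
                config.base_log_intensity + config.grade_log_step * g.index - 0.5 * U
            ) * area_km2
            for g in GRADES
        },
        index=ids,
    )
    retention = {
        "all": 1.0,
        "pre": config.frac_pre * (1.0 - config.frac_undated),
        "post": (1.0 - config.frac_pre) * (1.0 - config.frac_undated),
    }
    truth = GroundTruth(
        latent_confounder=pd.Series(U, index=ids),
        grades=pd.Series([g.value for g in grades], index=ids),
        expected_count_by_grade=ecg,
        retention=retention,
    )
    return SyntheticStudy(neighborhoods, tracts, tract_attributes, wells, truth, config)


def true_ate(truth: GroundTruth, pair: tuple[str, str] | tuple[Grade, Grade], period: str = "all") -> float:
    """True mean counterfactual count difference (worse − better) for a pair.

    Averaged over the comparison population — the neighborhoods whose
    realized grade is either member of the pair — and scaled by the
    period's date-retention fraction (Poisson thinning).
    """
    better, worse = (g.value if isinstance(g, Grade) else str(g) for g in pair)
    if (better, worse) not in (("A", "B"), ("B", "C"), ("C", "D")):
        raise ValueError(f"not an adjacent (better, worse) pair: {(better, worse)}")
    if period not in truth.retention:
        raise ValueError(f"unknown period {period!r}")
    pop = truth.grades.isin([better, worse])
    if not pop.any():
        raise ValueError(f"no neighborhoods with grades {better}/{worse}")
    diff = (
        truth.expected_count_by_grade.loc[pop, worse]
        - truth.expected_count_by_grade.loc[pop, better]
    )
    return float(diff.mean() * truth.retention[period])


def simulate_matched_scenario(
    n_per_arm: int = 400,
    effect: float = 2.0,
    seed: int = 0,
    confounding: float = 1.0,
):
    """Arm-level confounded scenario with an exactly known additive effect.

    One standard-normal carrier Z (exposed as ``median_home_value`` after an
    affine rescale) drives both the treatment mechanism,
    logit P(A=1|W) = −confounding·0.8·Z, and the baseline Poisson intensity
    λ0 = exp(0.7 − confounding·0.6·Z); treated units receive an additional
    independent intensity ``effect``, so the average treatment effect on the
    count scale is exactly ``effect`` for every unit.  The remaining nine
    covariates are noisy correlates of Z.  Returns ``(Y, A, W, effect)``
    with W a DataFrame using the census covariate names.
    """
    rng = np.random.default_rng(seed)
    n = 2 * n_per_arm
    z = rng.normal(0, 1, n)
    g = 1.0 / (1.0 + np.exp(confounding * 0.8 * z))
    a = (rng.random(n) < g).astype(int)
    lam0 = np.exp(0.7 - confounding * 0.6 * z)
    y = rng.poisson(lam0 + effect * a).astype(float)

    cols = {}
    for name, (b0, b1, sd, lo, hi) in _COV_MODEL.items():
        if name == "median_home_value":
            cols[name] = np.clip(b0 + 1500.0 * z, lo, hi)  # noiseless carrier
        else:
            cols[name] = np.clip(b0 + b1 * (-z) + rng.normal(0, 2 * sd, n), lo, hi)
    W = pd.DataFrame(cols)
    return y, a, W, float(effect)
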