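"""Synthetic phantoms and cohorts for the WMH shape pipeline.

No imaging data ships with the package; every pipeline stage is exercised on
synthetic inputs instead:

* **Phantoms** — 3D ventricle + lesion masks on a configurable grid.
  Ventricles are a pair of elongated digitized ellipsoid lobes; lesions are
  star-convex bodies whose boundary irregularity is controlled by a single
  knob ``kappa`` in [0, 1].
* **Cohorts** — tabular participant records (age, sex, shape markers, WMH
  and intracranial volumes, baseline and new-lesion outcome flags) drawn
  from distributions matching the published summary statistics of a large
  population cohort of older adults (n = 2297, age 74.5 +/- 4.7, 61% female,
  baseline WMH volume 16.56 +/- 17.21 ml), with configurable true effects
  so that the association stage can be validated by parameter recovery.

Lesion irregularity model
-------------------------
A lesion with ``kappa = 0`` is an exact digitized ellipsoid.  For
``kappa > 0`` the radius along each direction u is

    r(u) = r_ellipsoid(u) * max(1, 1 + kappa * A * g(u)) * (1 + G * kappa)

where g is a fixed band-limited zero-mean noise field on the sphere (sum of
random cosine waves, normalized to max |g| = 1, drawn from the lesion seed),
A is the protrusion amplitude and G a global size coupling.  Protrusions are
outward-only: irregular WMH grow finger-like extensions rather than losing
core volume, and irregular (confluent) lesions are also systematically
larger, which the size coupling reproduces.  The construction is star-convex,
hence always produces one connected component, and is monotone by design:
raising kappa lowers solidity and convexity and raises concavity index and
box-counting fractal dimension (checked on group medians in the test suite).

All generators are deterministic functions of their seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .mask_model import BinaryMask, VolumeGeometry, connected_components, distance_field

__all__ = [
    "LesionSpec",
    "PhantomSpec",
    "CohortSimConfig",
    "make_ventricles",
    "make_lesion",
    "make_participant_images",
    "simulate_cohort",
    "simulate_outcomes",
]

#: Default protrusion amplitude A, size coupling G, angular frequency and
#: number of cosine waves of the irregularity field.
LESION_AMPLITUDE = 0.35
LESION_SIZE_COUPLING = 0.7
LESION_NOISE_FREQ = 8.0
LESION_NOISE_WAVES = 12


@dataclass(frozen=True)
class LesionSpec:
    """One synthetic lesion: position, base ellipsoid, irregularity, seed."""

    center_mm: tuple[float, float, float]
    semi_axes_mm: tuple[float, float, float]
    kappa: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.kappa <= 1.0:
            raise ValueError("kappa must lie in [0, 1]")
        if any(a <= 0 for a in self.semi_axes_mm):
            raise ValueError("semi-axes must be positive")


@dataclass(frozen=True)
class PhantomSpec:
    """A participant phantom: grid, ventricle template and lesion list.

    The default 96 x 96 x 48 grid at 1 x 1 x 2 mm keeps full-pipeline tests
    fast; ``clinical_spacing()`` switches to the clinical FLAIR voxel size.
    """

    geometry: VolumeGeometry = field(
        default_factory=lambda: VolumeGeometry.from_spacing((96, 96, 48), (1.0, 1.0, 2.0))
    )
    ventricle_semi_axes_mm: tuple[float, float, float] = (4.0, 22.0, 5.0)
    ventricle_separation_mm: float = 16.0
    lesions: tuple[LesionSpec, ...] = ()
    seed: int = 0

    @staticmethod
    def clinical_spacing(shape=(128, 128, 36)) -> "PhantomSpec":
        return PhantomSpec(
            geometry=VolumeGeometry.from_spacing(shape, (0.86, 0.86, 3.0))
        )

    @property
    def center_mm(self) -> np.ndarray:
        return (np.array(self.geometry.shape) - 1) / 2.0 * self.geometry.spacing


def _voxel_centers_mm(geometry: VolumeGeometry) -> np.ndarray:
    idx = np.indices(geometry.shape).astype(float)
    sp = geometry.spacing
    return np.stack([idx[k] * sp[k] for k in range(3)], axis=-1)


def make_ventricles(spec: PhantomSpec) -> BinaryMask:
    """Two disjoint elongated ellipsoid lobes mimicking lateral ventricles."""
    geom = spec.geometry
    sa = np.asarray(spec.ventricle_semi_axes_mm, dtype=float)
    extent = np.array(geom.shape) * geom.spacing
    center = spec.center_mm
    half_sep = spec.ventricle_separation_mm / 2.0
    for sign in (-1, 1):
        lobe_c = center + np.array([sign * half_sep, 0.0, 0.0])
        if np.any(lobe_c - sa < 0) or np.any(lobe_c + sa > extent):
            raise ValueError("ventricle lobes exceed the phantom grid")
    X = _voxel_centers_mm(geom)
    mask = np.zeros(geom.shape, dtype=bool)
    for sign in (-1, 1):
        lobe_c = center + np.array([sign * half_sep, 0.0, 0.0])
        q = (((X - lobe_c) / sa) ** 2).sum(axis=-1)
        mask |= q <= 1.0
    out = BinaryMask(geom, mask)
    if out.n_voxels == 0:
        raise ValueError("ventricle template produced an empty mask")
    return out


def _noise_field(unit_dirs: np.ndarray, seed: int, valid: np.ndarray) -> np.ndarray:
    """Band-limited zero-mean directional noise, normalized to max |g| = 1."""
    rng = np.random.default_rng(seed)
    waves = rng.normal(size=(LESION_NOISE_WAVES, 3)) * LESION_NOISE_FREQ
    phases = rng.uniform(0.0, 2.0 * np.pi, LESION_NOISE_WAVES)
    amps = rng.normal(size=LESION_NOISE_WAVES)
    g = np.zeros(unit_dirs.shape[:-1])
    for w, p, a in zip(waves, phases, amps):
        g += a * np.cos((unit_dirs * w).sum(axis=-1) + p)
    g -= g[valid].mean()
    g /= np.abs(g[valid]).max() + 1e-12
    return g


def make_lesion(
    geometry: VolumeGeometry,
    center_mm,
    semi_axes_mm,
    kappa: float = 0.0,
    seed: int = 0,
    amplitude: float = LESION_AMPLITUDE,
    size_coupling: float = LESION_SIZE_COUPLING,
) -> BinaryMask:
    """Digitize one star-convex lesion into the given grid.

    ``kappa = 0`` yields the exact digitized ellipsoid regardless of seed.
    """
    if not 0.0 <= kappa <= 1.0:
        raise ValueError("kappa must lie in [0, 1]")
    sa = np.asarray(semi_axes_mm, dtype=float)
    center = np.asarray(center_mm, dtype=float)
    sp = geometry.spacing

    # Work on a local bounding region around the lesion for speed.
    reach = sa.max() * (1 + amplitude) * (1 + size_coupling) * 1.05 + sp.max()
    lo = np.maximum(np.floor((center - reach) / sp).astype(int), 0)
    hi = np.minimum(
        np.ceil((center + reach) / sp).astype(int) + 1, np.array(geometry.shape)
    )
    if np.any(lo >= hi):
        raise ValueError("lesion lies entirely outside the grid")
    idx = np.indices(tuple(hi - lo)).astype(float)
    X = np.stack([(idx[k] + lo[k]) * sp[k] - center[k] for k in range(3)], axis=-1)
    rr = np.linalg.norm(X, axis=-1)
    valid = rr > 0
    U = np.where(valid[..., None], X / np.where(rr[..., None] == 0, 1.0, rr[..., None]), 0.0)
    q = ((U / sa) ** 2).sum(axis=-1)
    r_ell = np.where(q > 0, 1.0 / np.sqrt(np.where(q == 0, 1.0, q)), np.inf)

    factor = 1.0 + size_coupling * kappa
    if kappa > 0:
        g = _noise_field(U, seed, valid)
        factor = np.maximum(1.0, 1.0 + kappa * amplitude * g) * factor
    local = rr <= r_ell * factor

    # The voxel holding the center is always part of the body.
    cvox = np.round(center / sp).astype(int) - lo
    if np.all((cvox >= 0) & (cvox < np.array(local.shape))):
        local[tuple(cvox)] = True

    data = np.zeros(geometry.shape, dtype=bool)
    data[tuple(slice(a, b) for a, b in zip(lo, hi))] = local
    mask = BinaryMask(geometry, data)
    if mask.n_voxels == 0:
        raise ValueError("lesion digitization produced an empty mask")
    return mask


def make_participant_images(
    spec: PhantomSpec,
) -> tuple[BinaryMask, BinaryMask, pd.DataFrame]:
    """Ventricle mask, WMH mask and per-lesion ground truth for one phantom.

    The WMH mask is the union of the lesions minus ventricle voxels.  Ground
    truth records each lesion's distance range to the ventricle surface and
    the implied type under the 3/10 mm rule, plus whether the lesion was
    clipped by the grid boundary.
    """
    vent = make_ventricles(spec)
    dist = distance_field(vent).values
    geom = spec.geometry
    extent = np.array(geom.shape) * geom.spacing

    wmh = np.zeros(geom.shape, dtype=bool)
    rows = []
    for i, lesion in enumerate(spec.lesions):
        m = make_lesion(
            geom, lesion.center_mm, lesion.semi_axes_mm, lesion.kappa, lesion.seed
        )
        body = m.data & ~vent.data
        if not body.any():
            raise ValueError(f"lesion {i} lies entirely inside the ventricles")
        d = dist[body]
        d_min, d_max = float(d.min()), float(d.max())
        if d_min > 3.0:
            truth = "deep"
        elif d_max > 10.0:
            truth = "confluent"
        else:
            truth = "periventricular"
        pts = np.argwhere(body)
        clipped = bool(
            (pts.min(axis=0) == 0).any()
            or (pts.max(axis=0) == np.array(geom.shape) - 1).any()
        )
        rep = pts[0]  # a voxel guaranteed to belong to this lesion
        rows.append(
            {
                "lesion": i,
                "kappa": lesion.kappa,
                "n_voxels": int(body.sum()),
                "dist_min_mm": d_min,
                "dist_max_mm": d_max,
                "truth_type": truth,
                "clipped": clipped,
                "rep_i": int(rep[0]),
                "rep_j": int(rep[1]),
                "rep_k": int(rep[2]),
            }
        )
        wmh |= body

    return vent, BinaryMask(geom, wmh), pd.DataFrame(rows)


# --- tabular cohort simulation ----------------------------------------------

#: Published summary statistics used as simulation defaults:
#: marker mean +/- sd, cohort size, demographics and outcome frequencies.
MARKER_DISTRIBUTIONS = {
    "solidity": (0.19, 0.12),
    "convexity": (1.03, 0.18),
    "concavity_index": (1.27, 0.15),
    "fd_pvc": (1.71, 0.15),
    "eccentricity": (0.61, 0.07),
    "fd_deep": (1.70, 0.14),
}

#: Cohort flow of the emulated study: participants included, and the
#: printed reasons participants were lost before follow-up imaging.
COHORT_N = 2297
MISSING_FOLLOWUP_REASONS = {
    "death": 505,
    "disability_or_refused": 859,
    "lost_to_followup": 104,
    "claustrophobia": 86,
    "mri_contraindications": 116,
    "technical_issues": 2,
}

#: outcome -> (participants positive at baseline, new cases at follow-up)
OUTCOME_COUNTS = {
    "subcortical_infarct": (153, 68),
    "microbleed": (381, 299),
    "epvs": (358, 39),
    "cerebellar_infarct": (434, 162),
    "cortical_infarct": (176, 123),
}

#: outcome -> (baseline prevalence, new-lesion incidence over follow-up)
OUTCOME_RATES = {
    "subcortical_infarct": (153 / 2297, 68 / 2297),
    "microbleed": (381 / 2297, 299 / 2297),
    "epvs": (358 / 2297, 39 / 2297),
    "cerebellar_infarct": (434 / 2297, 162 / 2297),
    "cortical_infarct": (176 / 2297, 123 / 2297),
}

#: Reference regression estimates used as default true effects: B (ml per SD)
#: for the WMH-volume-change model and OR per SD for each new-lesion outcome.
REFERENCE_LINEAR_SLOPES = {
    "solidity": 0.91,
    "convexity": 1.94,
    "concavity_index": 2.28,
    "fd_pvc": 2.62,
    "eccentricity": 2.02,
    "fd_deep": 2.09,
    "wmh_baseline_ml": 4.05,
}

REFERENCE_ODDS_RATIOS = {
    "subcortical_infarct": {
        "solidity": 1.75, "convexity": 1.44, "concavity_index": 1.58,
        "fd_pvc": 1.91, "eccentricity": 1.04, "fd_deep": 1.09,
        "wmh_baseline_ml": 2.26,
    },
    "microbleed": {
        "solidity": 1.24, "convexity": 1.16, "concavity_index": 1.24,
        "fd_pvc": 1.47, "eccentricity": 1.14, "fd_deep": 1.03,
        "wmh_baseline_ml": 1.52,
    },
    "epvs": {
        "solidity": 1.07, "convexity": 1.34, "concavity_index": 1.34,
        "fd_pvc": 1.28, "eccentricity": 0.97, "fd_deep": 1.04,
        "wmh_baseline_ml": 1.28,
    },
    "cerebellar_infarct": {
        "solidity": 0.99, "convexity": 1.16, "concavity_index": 1.16,
        "fd_pvc": 1.14, "eccentricity": 1.02, "fd_deep": 1.06,
        "wmh_baseline_ml": 1.25,
    },
    "cortical_infarct": {
        "solidity": 1.27, "convexity": 1.04, "concavity_index": 1.09,
        "fd_pvc": 1.20, "eccentricity": 1.30, "fd_deep": 1.31,
        "wmh_baseline_ml": 1.44,
    },
}


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """mu, sigma of a log-normal with the given arithmetic mean and sd."""
    sigma2 = math.log(1.0 + (sd / mean) ** 2)
    return math.log(mean) - sigma2 / 2.0, math.sqrt(sigma2)


@dataclass(frozen=True)
class CohortSimConfig:
    """Configuration of the tabular cohort simulator.

    Defaults reproduce the published cohort's marker distributions, outcome
    rates and regression estimates; effect sizes act on the same
    standardized predictors the association stage fits, so configured
    values are directly recoverable.
    """

    n: int = 2297
    age_mean: float = 74.5
    age_sd: float = 4.7
    prop_female: float = 0.61
    marker_distributions: dict = field(
        default_factory=lambda: dict(MARKER_DISTRIBUTIONS)
    )
    wmh_baseline_mean_ml: float = 16.56
    wmh_baseline_sd_ml: float = 17.21
    icv_mean_ml: float = 1500.0
    icv_sd_ml: float = 140.0
    icv_followup_jitter_ml: float = 10.0
    delta_wmh_intercept_ml: float = 5.76
    delta_wmh_noise_sd_ml: float = 6.5
    #: ml change per year of age and for female sex in the linear model
    delta_wmh_age_slope: float = 0.10
    delta_wmh_sex_effect: float = -0.30
    linear_slopes: dict = field(default_factory=lambda: dict(REFERENCE_LINEAR_SLOPES))
    odds_ratios: dict = field(
        default_factory=lambda: {k: dict(v) for k, v in REFERENCE_ODDS_RATIOS.items()}
    )
    outcome_rates: dict = field(default_factory=lambda: dict(OUTCOME_RATES))
    #: log-odds per year of age / for female sex in the logistic models
    logit_age_slope: float = 0.03
    logit_sex_effect: float = -0.10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 10:
            raise ValueError("cohort size must be at least 10")
        for name, (m, s) in self.marker_distributions.items():
            if s <= 0:
                raise ValueError(f"marker {name}: sd must be positive")
        for name, (p0, p1) in self.outcome_rates.items():
            if not (0 < p0 < 1 and 0 < p1 < 1):
                raise ValueError(f"outcome {name}: prevalences must be in (0,1)")
        if self.age_sd <= 0 or self.wmh_baseline_sd_ml <= 0:
            raise ValueError("scale parameters must be positive")


def _standardize_for_effects(df: pd.DataFrame, predictor: str) -> np.ndarray:
    """Predictor on the analysis scale: log, z-score, directional inversion.

    Mirrors the association stage's transform pipeline (including the sign
    flip of solidity, convexity and eccentricity) so configured effects are
    expressed per SD of the predictor the models actually fit, and are
    directly recoverable.
    """
    from .association import INVERTED_PREDICTORS, LOG100_PREDICTORS

    x = df[predictor].to_numpy(dtype=float)
    if predictor in LOG100_PREDICTORS:
        x = np.log(100.0 * x)
    z = (x - np.nanmean(x)) / np.nanstd(x, ddof=1)
    if predictor in INVERTED_PREDICTORS:
        z = -z
    # Participants without lesions of a type have no marker; they contribute
    # the population-average (zero) effect when generating outcomes.
    return np.nan_to_num(z, nan=0.0)


def simulate_outcomes(
    markers: pd.DataFrame, config: CohortSimConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Attach volumes and outcomes to a table of markers and demographics.

    The WMH-volume change is a linear model on the standardized markers; the
    binary new-lesion outcomes follow logistic models whose intercepts are
    solved (bisection on the simulated linear predictor) so that the
    realized incidence matches the configured rate.
    """
    df = markers.copy()
    n = len(df)

    z = {p: _standardize_for_effects(df, p) for p in config.linear_slopes}

    age_c = df["age"].to_numpy() - config.age_mean
    female = df["sex"].to_numpy()

    eta = np.zeros(n)
    for pred, slope in config.linear_slopes.items():
        eta += slope * z[pred]
    delta = (
        config.delta_wmh_intercept_ml
        + eta
        + config.delta_wmh_age_slope * age_c
        + config.delta_wmh_sex_effect * (female - female.mean())
        + rng.normal(0.0, config.delta_wmh_noise_sd_ml, n)
    )
    df["wmh_followup_ml"] = df["wmh_baseline_ml"] + delta

    df["icv_baseline_ml"] = rng.normal(config.icv_mean_ml, config.icv_sd_ml, n)
    df["icv_followup_ml"] = df["icv_baseline_ml"] + rng.normal(
        0.0, config.icv_followup_jitter_ml, n
    )

    for outcome, (p_base, p_new) in config.outcome_rates.items():
        df[f"baseline_{outcome}"] = (rng.uniform(size=n) < p_base).astype(int)
        lp = config.logit_age_slope * age_c + config.logit_sex_effect * (
            female - female.mean()
        )
        for pred, or_value in config.odds_ratios.get(outcome, {}).items():
            lp = lp + math.log(or_value) * z[pred]
        alpha = _solve_intercept(lp, p_new)
        prob = 1.0 / (1.0 + np.exp(-(alpha + lp)))
        df[f"new_{outcome}"] = (rng.uniform(size=n) < prob).astype(int)
    return df


def _solve_intercept(lp: np.ndarray, target: float) -> float:
    """Intercept such that mean sigmoid(alpha + lp) equals the target rate."""
    lo, hi = -30.0, 30.0
    for _ in range(80):
        mid = (lo + hi) / 2.0
        if np.mean(1.0 / (1.0 + np.exp(-(mid + lp)))) < target:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


def simulate_cohort(config: CohortSimConfig | None = None) -> pd.DataFrame:
    """Draw a full synthetic participant table, reproducible from the seed.

    Markers are drawn independently per participant: solidity and baseline
    WMH volume log-normally (both are analysed on a log scale and must be
    positive), the remaining markers normally, truncated away from zero
    where the formula requires positivity.
    """
    config = config or CohortSimConfig()
    rng = np.random.default_rng(config.seed)
    n = config.n

    df = pd.DataFrame(
        {
            "id": [f"P{i:05d}" for i in range(n)],
            "age": rng.normal(config.age_mean, config.age_sd, n),
            "sex": (rng.uniform(size=n) < config.prop_female).astype(int),
        }
    )
    for name, (mean, sd) in config.marker_distributions.items():
        if name == "solidity":
            mu, sigma = _lognormal_params(mean, sd)
            df[name] = rng.lognormal(mu, sigma, n)
        else:
            df[name] = np.maximum(rng.normal(mean, sd, n), 0.01)
    mu, sigma = _lognormal_params(config.wmh_baseline_mean_ml, config.wmh_baseline_sd_ml)
    df["wmh_baseline_ml"] = rng.lognormal(mu, sigma, n)

    return simulate_outcomes(df, config, rng)
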