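"""Synthetic-data generators.

Two generators make every stage of the package testable without any
external data:

* :func:`simulate_latent_axis` — the textbook two-trait latent-variable
  model: traits uniform on an interval, a latent score
  ``y' = b0 + b1 t1 + b2 t2 + eps`` with standard-logistic noise, and the
  binary environment assigned by the sign of ``y'``.  By construction the
  conditional law is exactly ``logit P(E=B|T) = b0 + b1 t1 + b2 t2``, so a
  logistic fit should recover the generating coefficients.

* :func:`simulate_phase_population` — a two-phase locust-like population
  in which behavioral (fast) traits respond to crowding within hours while
  morphometric (slow) traits stay at natal-phase values; optional
  pathological structure mirrors what real assay datasets can contain: a
  near-perfectly collinear derived trait, a sign-encoding redundant trait,
  and an anomalous hind-femur ratio between phases.

A third helper simulates two-strain populations with identical or
strain-specific coefficient vectors for the pooling-vs-strain-specific
model comparison.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .phenotypes import PhenotypeError, PhenotypeTable, TraitMeta


def _logistic_noise(rng: np.random.Generator, n: int, scale: float) -> np.ndarray:
    # inverse-CDF of uniform draws: reproducible across platforms at fixed seed
    if scale == 0.0:
        return np.zeros(n)
    u = rng.uniform(0.0, 1.0, size=n)
    u = np.clip(u, 1e-12, 1 - 1e-12)
    return scale * np.log(u / (1.0 - u))


# ---------------------------------------------------------------------------
# latent-axis simulation


@dataclass(frozen=True)
class LatentSimConfig:
    N: int = 800
    beta0: float = 0.0
    beta1: float = 2.5
    beta2: float = 5.0
    trait_low: float = -0.5
    trait_high: float = 0.5
    noise_scale: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.trait_low >= self.trait_high:
            raise PhenotypeError("trait_low must be < trait_high")
        if self.noise_scale < 0:
            raise PhenotypeError("noise_scale must be >= 0")


def simulate_latent_axis(config: LatentSimConfig = LatentSimConfig()) -> PhenotypeTable:
    """Simulate the two-trait latent-axis population.

    Each individual gets independent uniform traits (t1, t2), a latent
    score ``y' = b0 + b1 t1 + b2 t2 + eps`` with logistic noise, and
    environment B iff ``y' > 0`` (A otherwise).
    """
    rng = np.random.default_rng(config.seed)
    t1 = rng.uniform(config.trait_low, config.trait_high, size=config.N)
    t2 = rng.uniform(config.trait_low, config.trait_high, size=config.N)
    eps = _logistic_noise(rng, config.N, config.noise_scale)
    y_latent = config.beta0 + config.beta1 * t1 + config.beta2 * t2 + eps
    env = np.where(y_latent > 0, "B", "A")
    data = pd.DataFrame({"environment": env, "t1": t1, "t2": t2})
    meta = {
        "t1": TraitMeta(domain="behavioral", timescale="fast"),
        "t2": TraitMeta(domain="behavioral", timescale="fast"),
    }
    return PhenotypeTable(data=data, environment="environment", trait_meta=meta)


# ---------------------------------------------------------------------------
# two-phase locust-like population


@dataclass(frozen=True)
class TraitSpec:
    name: str
    domain: str  # behavioral | morphometric
    timescale: str  # fast | slow
    sol_mean: float
    sol_sd: float
    greg_mean: float
    greg_sd: float


@dataclass(frozen=True)
class CollinearPair:
    base: str
    derived: str
    r: float = 0.9998


@dataclass(frozen=True)
class SignRedundantPair:
    base: str
    derived: str


def default_phase_traits() -> tuple[TraitSpec, ...]:
    """Shape-alike trait set mimicking a final-instar assay dataset:
    8 base behavioral variables and 3 morphometrics (plus 2 derived
    columns added by the generator gives 13 candidate predictors)."""
    return (
        TraitSpec("average_speed", "behavioral", "fast", 1.0, 0.45, 1.6, 0.55),
        TraitSpec("erratic_movement", "behavioral", "fast", 0.20, 0.10, 0.50, 0.15),
        TraitSpec("stop_ratio", "behavioral", "fast", 0.60, 0.15, 0.30, 0.12),
        TraitSpec("turn_ratio", "behavioral", "fast", 0.45, 0.12, 0.35, 0.12),
        TraitSpec("activity_fraction", "behavioral", "fast", 0.25, 0.12, 0.65, 0.15),
        TraitSpec("distance_covered", "behavioral", "fast", 40.0, 18.0, 95.0, 30.0),
        TraitSpec("last_coordinate", "behavioral", "fast", -8.0, 6.0, 6.0, 7.0),
        TraitSpec("attraction_index", "behavioral", "fast", -2.0, 0.5, 2.0, 0.5),
        TraitSpec("hind_femur_length", "morphometric", "slow", 11.0, 0.9, 9.9, 1.2),
        TraitSpec("pronotum_width", "morphometric", "slow", 4.2, 0.35, 4.6, 0.40),
        TraitSpec("head_width", "morphometric", "slow", 3.4, 0.30, 3.9, 0.32),
    )


@dataclass(frozen=True)
class PhasePopConfig:
    """Two-phase population layout.

    ``femur_ratio`` sets the gregarious/solitarious mean hind-femur-length
    ratio: 0.9 is the normal situation (gregarious desert locusts have
    relatively shorter hind femora); 1.6 reproduces the anomalous dataset
    in which gregarious nymphs are both faster AND longer-legged, the
    scenario in which ratio "normalization" of speed destroys its
    predictive signal.

    ``crowding_hours`` applies to the solitarious cohort: fast behavioral
    traits move toward the gregarious distribution following a saturating
    exponential with half-time ``crowding_half_time_h`` (hours); slow
    morphometric traits never move.
    """

    n_solitarious: int = 15
    n_gregarious: int = 51
    traits: tuple[TraitSpec, ...] = field(default_factory=default_phase_traits)
    crowding_hours: float = 0.0
    crowding_half_time_h: float = 4.0
    femur_ratio: float = 0.9
    size_trait: str = "hind_femur_length"
    collinear_pair: CollinearPair | None = CollinearPair(
        base="average_speed", derived="average_acceleration"
    )
    sign_redundant_pair: SignRedundantPair | None = SignRedundantPair(
        base="last_coordinate", derived="final_choice"
    )
    seed: int = 0

    def __post_init__(self) -> None:
        for t in self.traits:
            if t.sol_sd <= 0 or t.greg_sd <= 0:
                raise PhenotypeError(f"trait {t.name!r} has non-positive SD")
        if self.collinear_pair is not None and not (0 < self.collinear_pair.r <= 1):
            raise PhenotypeError(
                f"collinearity target r={self.collinear_pair.r} not in (0, 1]"
            )
        if self.crowding_half_time_h <= 0:
            raise PhenotypeError("crowding half-time must be positive")


def crowding_response(hours: np.ndarray | float, half_time_h: float) -> np.ndarray:
    """Saturating fractional shift toward the gregarious trait value:
    0 at 0 h, 1/2 at one half-time, -> 1 as hours -> infinity."""
    h = np.asarray(hours, dtype=float)
    return 1.0 - np.exp2(-h / half_time_h)


def simulate_phase_population(config: PhasePopConfig = PhasePopConfig()) -> PhenotypeTable:
    """Draw a two-phase population with decoupled trait timescales.

    Solitarious individuals crowded for ``crowding_hours`` have their fast
    (behavioral) trait means and SDs interpolated toward the gregarious
    parameters by the saturating crowding response; slow (morphometric)
    traits stay at natal-phase parameters regardless of crowding.
    """
    rng = np.random.default_rng(config.seed)
    n_sol, n_greg = config.n_solitarious, config.n_gregarious
    n = n_sol + n_greg
    phase = np.array(["solitarious"] * n_sol + ["gregarious"] * n_greg)
    hours = np.concatenate(
        [np.full(n_sol, float(config.crowding_hours)), np.zeros(n_greg)]
    )
    f_shift = crowding_response(hours, config.crowding_half_time_h)

    cols: dict[str, np.ndarray] = {}
    meta: dict[str, TraitMeta] = {}
    for t in config.traits:
        greg_mean, greg_sd = t.greg_mean, t.greg_sd
        if t.name == config.size_trait:
            greg_mean = config.femur_ratio * t.sol_mean
        mean = np.where(phase == "gregarious", greg_mean, t.sol_mean).astype(float)
        sd = np.where(phase == "gregarious", greg_sd, t.sol_sd).astype(float)
        if t.timescale == "fast":
            # crowded solitarious individuals drift toward gregarious values
            mean = mean + np.where(
                phase == "solitarious", f_shift * (greg_mean - t.sol_mean), 0.0
            )
            sd = sd + np.where(
                phase == "solitarious", f_shift * (greg_sd - t.sol_sd), 0.0
            )
        cols[t.name] = rng.normal(mean, sd)
        meta[t.name] = TraitMeta(domain=t.domain, timescale=t.timescale)

    if config.collinear_pair is not None:
        cp = config.collinear_pair
        if cp.base not in cols:
            raise PhenotypeError(f"collinear base trait {cp.base!r} not generated")
        base = cols[cp.base]
        r = cp.r
        if r == 1.0:
            jitter = np.zeros(n)
        else:
            # var(jitter) solved from the correlation target:
            # r^2 = var(base) / (var(base) + var(jitter))
            sd_b = float(np.std(base, ddof=1))
            jitter = rng.normal(0.0, sd_b * np.sqrt(1.0 / r**2 - 1.0), size=n)
        base_meta = meta[cp.base]
        cols[cp.derived] = 0.8 * (base + jitter) + 0.1
        meta[cp.derived] = TraitMeta(base_meta.domain, base_meta.timescale)

    if config.sign_redundant_pair is not None:
        sp = config.sign_redundant_pair
        if sp.base not in cols:
            raise PhenotypeError(f"sign-redundancy base trait {sp.base!r} not generated")
        cols[sp.derived] = np.where(cols[sp.base] > 0, 1.0, -1.0)
        base_meta = meta[sp.base]
        meta[sp.derived] = TraitMeta(base_meta.domain, base_meta.timescale)

    data = pd.DataFrame({"phase": phase, "crowding_hours": hours, **cols})
    table = PhenotypeTable(data=data, environment="phase", trait_meta=meta)
    # provenance for reproducibility
    table.data.attrs["config"] = asdict(config)
    return table


# ---------------------------------------------------------------------------
# two-strain populations for the pooling comparison


def simulate_strain_population(
    n_per_strain: int,
    beta_a: np.ndarray,
    beta_b: np.ndarray,
    seed: int = 0,
    strain_names: tuple[str, str] = ("A", "B"),
) -> PhenotypeTable:
    """Two strains with standard-normal predictors and strain-specific
    logistic coefficient vectors ``beta = (b0, b1, ..., bk)``.

    Phase is assigned by the latent-score rule (gregarious iff
    ``b0 + x.b + eps > 0`` with standard-logistic eps), so
    ``logit P(gregarious | x) = b0 + x.b`` within each strain.
    """
    beta_a = np.asarray(beta_a, dtype=float)
    beta_b = np.asarray(beta_b, dtype=float)
    if beta_a.shape != beta_b.shape or beta_a.ndim != 1 or len(beta_a) < 2:
        raise PhenotypeError("beta_a and beta_b must be equal-length vectors (b0, b1, ...)")
    k = len(beta_a) - 1
    rng = np.random.default_rng(seed)
    frames = []
    for name, beta in zip(strain_names, (beta_a, beta_b)):
        x = rng.normal(size=(n_per_strain, k))
        eta = beta[0] + x @ beta[1:]
        y_latent = eta + _logistic_noise(rng, n_per_strain, 1.0)
        phase = np.where(y_latent > 0, "gregarious", "solitarious")
        df = pd.DataFrame(x, columns=[f"x{i + 1}" for i in range(k)])
        df.insert(0, "strain", name)
        df.insert(0, "phase", phase)
        frames.append(df)
    data = pd.concat(frames, ignore_index=True)
    meta = {
        f"x{i + 1}": TraitMeta(domain="behavioral", timescale="fast") for i in range(k)
    }
    return PhenotypeTable(data=data, environment="phase", trait_meta=meta, strain="strain")


# ---------------------------------------------------------------------------
# fixture suite


def _repr_float(v) -> str:
    return repr(float(v))


def _write_meta(meta: dict[str, TraitMeta], path: Path) -> None:
    payload = {
        name: {"domain": m.domain, "timescale": m.timescale} for name, m in meta.items()
    }
    path.write_text(yaml.safe_dump(payload, sort_keys=True))


def write_fixture_suite(outdir: str | Path, seed: int = 0) -> dict:
    """Write the canonical fixture set and a manifest of seeds/configs.

    Fixtures: the latent-axis table; the anomaly-scenario two-phase table
    (15 solitarious / 51 gregarious, collinear and sign-redundant columns,
    femur ratio 1.6); and two-strain tables with and without a strain
    effect.  Deterministic: the same seed yields byte-identical files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": seed, "fixtures": {}}

    fig_cfg = LatentSimConfig(seed=seed)
    fig = simulate_latent_axis(fig_cfg)
    fig.data.to_csv(outdir / "latent_axis.csv", index=False, float_format=_repr_float)
    _write_meta(fig.trait_meta, outdir / "latent_axis_meta.yaml")
    manifest["fixtures"]["latent_axis"] = {
        "csv": "latent_axis.csv",
        "meta": "latent_axis_meta.yaml",
        "config": asdict(fig_cfg),
    }

    pop_cfg = PhasePopConfig(femur_ratio=1.6, seed=seed + 1)
    pop = simulate_phase_population(pop_cfg)
    pop.data.to_csv(outdir / "phase_population_anomaly.csv", index=False, float_format=_repr_float)
    _write_meta(pop.trait_meta, outdir / "phase_population_anomaly_meta.yaml")
    manifest["fixtures"]["phase_population_anomaly"] = {
        "csv": "phase_population_anomaly.csv",
        "meta": "phase_population_anomaly_meta.yaml",
        "config": asdict(pop_cfg),
    }

    beta = np.array([0.0, 1.0, -0.8, 0.6])
    null_tab = simulate_strain_population(120, beta, beta, seed=seed + 2)
    null_tab.data.to_csv(outdir / "strain_null.csv", index=False, float_format=_repr_float)
    _write_meta(null_tab.trait_meta, outdir / "strain_null_meta.yaml")
    manifest["fixtures"]["strain_null"] = {
        "csv": "strain_null.csv",
        "meta": "strain_null_meta.yaml",
        "config": {"n_per_strain": 120, "beta_a": beta.tolist(), "beta_b": beta.tolist(),
                   "seed": seed + 2},
    }

    beta_b = beta.copy()
    beta_b[1] = -beta_b[1]  # sign-flipped first coefficient in strain B
    eff_tab = simulate_strain_population(120, beta, beta_b, seed=seed + 3)
    eff_tab.data.to_csv(outdir / "strain_effect.csv", index=False, float_format=_repr_float)
    _write_meta(eff_tab.trait_meta, outdir / "strain_effect_meta.yaml")
    manifest["fixtures"]["strain_effect"] = {
        "csv": "strain_effect.csv",
        "meta": "strain_effect_meta.yaml",
        "config": {"n_per_strain": 120, "beta_a": beta.tolist(), "beta_b": beta_b.tolist(),
                   "seed": seed + 3},
    }

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
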