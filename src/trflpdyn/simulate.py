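"""Synthetic fingerprint and covariate generator with known planted structure.

Emulates a year-long activated-sludge monitoring campaign: two dozen samples
taken at 15-day intervals, a handful of dominant T-RFs plus sub-noise-floor
spurious peaks, and operational covariates following stationary AR(1)
processes.  Taxon abundances respond unimodally (Gaussian response curves) to
a named driver covariate,

    a_kt = h_k * exp(-(x_t - u_k)^2 / (2 t_k^2)),

with optimum ``u_k``, tolerance ``t_k`` and maximum height ``h_k`` in driver
units; profiles are the a_kt normalized across taxa.  Unimodal responses are
the standard ecological model behind correspondence-analysis ordination, which
is why the downstream CCA stage can recover the planted driver.

Every stochastic draw flows from the scenario's single integer seed through
named :class:`numpy.random.SeedSequence` children, so outputs are bit-identical
across runs and stages can be re-run independently.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import yaml

from .profiles import MAX_TRF_BP, MIN_TRF_BP, CommunityProfile, ProfileSeries

_STAGE_STREAMS = {"env": 0, "profiles": 1, "render": 2}


@dataclass(frozen=True)
class EnvSpec:
    """Stationary AR(1) covariate: mean, stationary sd, lag-1 coefficient rho.

    ``lower`` clips the emitted series from below — concentrations cannot go
    negative, and a plant running near-complete nitrification really does sit
    at the detection floor part of the time.  Clipping slightly shrinks the
    realized sd of variables with mass near the bound.
    """

    mean: float
    sd: float
    rho: float = 0.0
    lower: float | None = None
    upper: float | None = None


@dataclass(frozen=True)
class ResponseSpec:
    """Gaussian (unimodal) response of one taxon to a driver covariate."""

    driver: str
    optimum: float  # u_k, driver units
    tolerance: float  # t_k, driver units; > 0
    height: float = 1.0  # h_k, maximum unnormalized abundance; > 0


@dataclass
class SyntheticScenario:
    """Full description of a synthetic monitoring campaign."""

    n_samples: int = 24
    interval_days: float = 15.0
    trf_lengths_bp: tuple[int, ...] = (219, 354, 491)
    env_specs: dict[str, EnvSpec] = field(default_factory=dict)
    response_specs: dict[int, ResponseSpec] = field(default_factory=dict)
    n_noise_peaks: int = 0
    max_noise_abundance: float = 0.015  # strictly below the 2% noise floor
    length_jitter_sd: float = 0.0  # bp
    total_area: float = 50_000.0  # fluorescence units
    dirichlet_concentration: float | None = None  # compositional counting noise
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2")
        if self.interval_days <= 0:
            raise ValueError("interval_days must be > 0")
        if len(set(self.trf_lengths_bp)) != len(self.trf_lengths_bp):
            raise ValueError("trf_lengths_bp must be distinct")
        for b in self.trf_lengths_bp:
            if not (MIN_TRF_BP <= b <= MAX_TRF_BP):
                raise ValueError(f"T-RF length {b} outside [{MIN_TRF_BP}, {MAX_TRF_BP}]")
        for b, spec in self.response_specs.items():
            if b not in self.trf_lengths_bp:
                raise ValueError(f"response for unknown T-RF {b}")
            if spec.tolerance <= 0:
                raise ValueError(f"T-RF {b}: tolerance must be > 0")
            if spec.height <= 0:
                raise ValueError(f"T-RF {b}: height must be > 0")
        if not (0 <= self.max_noise_abundance < 0.02):
            raise ValueError("max_noise_abundance must lie in [0, 0.02)")

    @property
    def n_taxa(self) -> int:
        return len(self.trf_lengths_bp)

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) * self.interval_days

    @property
    def sample_ids(self) -> list[str]:
        return [f"d{int(t):03d}" for t in self.times]

    def rng(self, stage: str) -> np.random.Generator:
        """Stage-specific generator derived deterministically from the one seed."""
        children = np.random.SeedSequence(self.seed).spawn(len(_STAGE_STREAMS))
        return np.random.default_rng(children[_STAGE_STREAMS[stage]])

    # ---- scenario file round-trip (YAML; JSON is a YAML subset) ----

    def to_file(self, path) -> None:
        data = asdict(self)
        data["trf_lengths_bp"] = list(self.trf_lengths_bp)
        data["response_specs"] = {int(k): v for k, v in data["response_specs"].items()}
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)

    @classmethod
    def from_file(cls, path) -> "SyntheticScenario":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        data["trf_lengths_bp"] = tuple(data["trf_lengths_bp"])
        data["env_specs"] = {k: EnvSpec(**v) for k, v in data["env_specs"].items()}
        data["response_specs"] = {
            int(k): ResponseSpec(**v) for k, v in data["response_specs"].items()
        }
        return cls(**data)


def simulate_env_series(scenario: SyntheticScenario) -> pd.DataFrame:
    """Stationary AR(1) series for every covariate in the scenario.

    x_t = mean + rho * (x_{t-1} - mean) + eps_t with innovation sd chosen as
    sd * sqrt(1 - rho^2) so the stationary sd equals the spec's sd; x_0 is
    drawn from the stationary distribution.
    """
    rng = scenario.rng("env")
    out = {"sample_id": scenario.sample_ids, "time_days": scenario.times}
    for name, spec in scenario.env_specs.items():
        if abs(spec.rho) >= 1:
            raise ValueError(f"env variable {name!r}: |rho| must be < 1 (stationarity)")
        innov_sd = spec.sd * np.sqrt(1.0 - spec.rho**2)
        x = np.empty(scenario.n_samples)
        x[0] = spec.mean + spec.sd * rng.standard_normal()
        eps = innov_sd * rng.standard_normal(scenario.n_samples - 1)
        for t in range(1, scenario.n_samples):
            x[t] = spec.mean + spec.rho * (x[t - 1] - spec.mean) + eps[t - 1]
        if spec.lower is not None:
            x = np.maximum(x, spec.lower)
        if spec.upper is not None:
            x = np.minimum(x, spec.upper)
        out[name] = x
    return pd.DataFrame(out)


def simulate_profile_series(
    scenario: SyntheticScenario, env: pd.DataFrame
) -> ProfileSeries:
    """Gaussian-response abundances normalized to compositions.

    Deterministic given ``env`` unless ``dirichlet_concentration`` is set, in
    which case each profile is resampled from Dirichlet(concentration * p) to
    emulate compositional counting noise.
    """
    if len(env) != scenario.n_samples:
        raise ValueError(
            f"env has {len(env)} rows, scenario expects {scenario.n_samples}"
        )
    raw = np.zeros((scenario.n_samples, scenario.n_taxa))
    for j, trf in enumerate(scenario.trf_lengths_bp):
        spec = scenario.response_specs.get(trf)
        if spec is None:
            raise ValueError(f"no response spec for T-RF {trf}")
        if spec.driver not in env.columns:
            raise ValueError(f"driver variable {spec.driver!r} missing from env table")
        x = env[spec.driver].to_numpy(dtype=float)
        raw[:, j] = spec.height * np.exp(
            -((x - spec.optimum) ** 2) / (2.0 * spec.tolerance**2)
        )
    probs = raw / raw.sum(axis=1, keepdims=True)
    if scenario.dirichlet_concentration is not None:
        rng = scenario.rng("profiles")
        probs = np.vstack(
            [rng.dirichlet(scenario.dirichlet_concentration * p) for p in probs]
        )
    profiles = []
    for i, (sid, t) in enumerate(zip(scenario.sample_ids, scenario.times)):
        abund = {
            int(b): float(probs[i, j]) for j, b in enumerate(scenario.trf_lengths_bp)
        }
        profiles.append(CommunityProfile(sid, float(t), abund))
    return ProfileSeries(profiles)


def render_peak_tables(
    series: ProfileSeries, scenario: SyntheticScenario
) -> pd.DataFrame:
    """Turn profiles into a raw peak table: areas, length jitter, noise peaks.

    Each taxon becomes a peak with area = relative abundance x total_area and
    fragment length = bin label + Gaussian jitter.  Noise peaks are placed at
    random lengths in the sizing window, at least 2 bp away from any true bin,
    with relative abundance strictly below the noise floor.
    """
    rng = scenario.rng("render")
    true_bins = np.asarray(scenario.trf_lengths_bp, dtype=float)
    rows: list[tuple[str, float, float, float]] = []
    for prof in series:
        for b, p in sorted(prof.abundances.items()):
            length = float(b) + scenario.length_jitter_sd * rng.standard_normal()
            rows.append((prof.sample_id, prof.time_days, length, p * scenario.total_area))
        for _ in range(scenario.n_noise_peaks):
            while True:
                length = rng.uniform(MIN_TRF_BP, MAX_TRF_BP)
                if np.abs(true_bins - length).min() > 2.0:
                    break
            frac = rng.uniform(0.1, 1.0) * scenario.max_noise_abundance
            rows.append((prof.sample_id, prof.time_days, length, frac * scenario.total_area))
    return pd.DataFrame(
        rows, columns=["sample_id", "time_days", "fragment_length", "area"]
    )


def fixed_similarity_series(
    n_samples: int,
    target_r: float,
    seed: int = 0,
    *,
    n_bins: int = 3,
    interval_days: float = 15.0,
) -> ProfileSeries:
    """Profiles whose every consecutive pair has Pearson correlation ``target_r``.

    Construction: profiles are uniform compositions displaced along a unit
    circle inside the zero-sum subspace of bin space; consecutive displacement
    directions differ by the fixed angle arccos(target_r), and Pearson
    correlation between two profiles equals the cosine of that angle exactly.
    Serves as an analytic oracle for the moving-window statistic: every change
    value is 100 * (1 - target_r) percent.
    """
    if not (-1.0 < target_r <= 1.0):
        raise ValueError("target_r must lie in (-1, 1]")
    if n_bins < 3:
        raise ValueError("need >= 3 bins")
    if n_samples < 2:
        raise ValueError("need >= 2 samples")
    # Orthonormal pair spanning a 2-D slice of the zero-sum subspace.
    e1 = np.zeros(n_bins)
    e1[0], e1[1] = 1.0, -1.0
    e1 /= np.linalg.norm(e1)
    e2 = np.full(n_bins, 1.0)
    e2[0] = e2[1] = -(n_bins - 2) / 2.0
    e2 /= np.linalg.norm(e2)
    theta = float(np.arccos(np.clip(target_r, -1.0, 1.0)))
    rng = np.random.default_rng(seed)
    phi0 = rng.uniform(0.0, 2.0 * np.pi)
    base = 1.0 / n_bins
    # Largest displacement keeping all components strictly positive.
    max_coord = max(
        np.abs(np.cos(a) * e1 + np.sin(a) * e2).max()
        for a in np.linspace(0, 2 * np.pi, 721)
    )
    eps = 0.8 * base / max_coord
    bins = [int(b) for b in np.linspace(MIN_TRF_BP + 10, MAX_TRF_BP - 10, n_bins)]
    profiles = []
    for t in range(n_samples):
        a = phi0 + t * theta
        p = base + eps * (np.cos(a) * e1 + np.sin(a) * e2)
        if (p <= 0).any():
            raise ValueError(
                f"target_r={target_r} infeasible under compositional constraints"
            )
        p = p / p.sum()
        profiles.append(
            CommunityProfile(
                f"d{int(t * interval_days):03d}",
                t * interval_days,
                {b: float(v) for b, v in zip(bins, p)},
            )
        )
    return ProfileSeries(profiles)


# ---------------------------------------------------------------------------
# Presets: the study conditions every downstream test runs under.
# ---------------------------------------------------------------------------

#: Operational covariate roster with magnitudes typical of a municipal
#: activated-sludge plant with near-complete nitrification: low effluent
#: ammonia/nitrite, ~26 mg/L effluent nitrate, strongly autocorrelated
#: seasonal temperature.
_DEFAULT_ENV_SPECS: dict[str, EnvSpec] = {
    "influent_BOD": EnvSpec(220.0, 35.0, 0.3, lower=0.0),
    "effluent_BOD": EnvSpec(8.0, 3.0, 0.3, lower=0.0),
    "influent_NH3": EnvSpec(35.0, 6.0, 0.3, lower=0.0),
    "effluent_NH3": EnvSpec(1.5, 1.0, 0.4, lower=0.0),
    "effluent_NO2": EnvSpec(0.4, 0.25, 0.2, lower=0.0),
    "effluent_NO3": EnvSpec(26.0, 4.0, 0.3, lower=0.0),
    "NH3_removal_eff": EnvSpec(95.0, 3.0, 0.3, lower=0.0, upper=100.0),
    "DO": EnvSpec(2.5, 0.8, 0.4, lower=0.0),
    "temperature": EnvSpec(20.0, 6.0, 0.9),
    "SVI": EnvSpec(120.0, 30.0, 0.5, lower=0.0),
    "MLSS": EnvSpec(3.5, 0.6, 0.5, lower=0.0),
    "SRT": EnvSpec(15.0, 3.0, 0.5, lower=0.0),
}

#: Temperature-driven Gaussian responses for the three dominant T-RFs; optima
#: and tolerances chosen so every taxon stays above the 2% noise floor over
#: the plausible temperature range, which makes the preprocessing round trip
#: exact by construction.
_DEFAULT_RESPONSES: dict[int, ResponseSpec] = {
    219: ResponseSpec("temperature", optimum=14.0, tolerance=10.0, height=1.0),
    354: ResponseSpec("temperature", optimum=26.0, tolerance=10.0, height=1.0),
    491: ResponseSpec("temperature", optimum=20.0, tolerance=12.0, height=0.5),
}


def noise_free_scenario(seed: int = 0) -> SyntheticScenario:
    """24 samples / 15-day interval, 3 dominant T-RFs, no jitter, no noise peaks."""
    return SyntheticScenario(
        n_samples=24,
        interval_days=15.0,
        trf_lengths_bp=(219, 354, 491),
        env_specs=dict(_DEFAULT_ENV_SPECS),
        response_specs=dict(_DEFAULT_RESPONSES),
        n_noise_peaks=0,
        length_jitter_sd=0.0,
        seed=seed,
    )


def default_scenario(seed: int = 0) -> SyntheticScenario:
    """Like :func:`noise_free_scenario` plus sizing jitter and sub-floor noise peaks."""
    sc = noise_free_scenario(seed)
    sc.n_noise_peaks = 3
    sc.max_noise_abundance = 0.015
    sc.length_jitter_sd = 0.15
    return sc


def dirty_scenario(seed: int = 0) -> SyntheticScenario:
    """Negative-control preset: noise peaks allowed up to the 2% floor boundary."""
    sc = default_scenario(seed)
    sc.max_noise_abundance = 0.0199
    sc.n_noise_peaks = 6
    return sc


def planted_driver_scenario(seed: int = 0, n_decoys: int = 5) -> SyntheticScenario:
    """Driver-recovery preset: temperature drives the taxa; decoys are pure AR(1) noise."""
    env_specs: dict[str, EnvSpec] = {"temperature": _DEFAULT_ENV_SPECS["temperature"]}
    # decoys are iid white noise: permutation tests assume exchangeability,
    # which autocorrelated covariates would violate (see the methods note)
    for i in range(n_decoys):
        env_specs[f"decoy_{i + 1}"] = EnvSpec(0.0, 1.0, 0.0)
    return SyntheticScenario(
        n_samples=24,
        interval_days=15.0,
        trf_lengths_bp=(219, 354, 491),
        env_specs=env_specs,
        response_specs=dict(_DEFAULT_RESPONSES),
        n_noise_peaks=0,
        length_jitter_sd=0.0,
        seed=seed,
    )


def simulate_campaign(
    scenario: SyntheticScenario,
) -> tuple[pd.DataFrame, ProfileSeries, pd.DataFrame]:
    """Convenience: env table, true profile series and rendered peak table."""
    env = simulate_env_series(scenario)
    series = simulate_profile_series(scenario, env)
    peaks = render_peak_tables(series, scenario)
    return env, series, peaks
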