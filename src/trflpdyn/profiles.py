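"""Core data containers for T-RFLP community profiles.

A community fingerprint is a vector of relative abundances over terminal
restriction fragment (T-RF) length bins.  A :class:`CommunityProfile` holds one
sample; a :class:`ProfileSeries` holds a time-ordered collection of samples
over the union of their bins and exposes the samples x bins matrix that the
ordination and distance modules consume.

Environmental/operational covariates travel as a plain :class:`pandas.DataFrame`
("env table") with one row per sample, a ``sample_id`` column, a ``time_days``
column and one column per variable (see :data:`ENV_VARIABLES` for the
operational roster of an activated-sludge nitrification study).  Missing values
are NaN and are never silently imputed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Operational / environmental covariates monitored alongside the fingerprints
#: in an activated-sludge nitrification study: biochemical oxygen demand (BOD,
#: mg/L) in and out, ammonia (mg/L) in and out, effluent nitrite and nitrate
#: (mg/L), ammonia removal efficiency (%), dissolved oxygen (DO, mg/L),
#: temperature (degC), sludge volume index (SVI, mL/g), mixed liquor suspended
#: solids (MLSS, g/L) and solids retention time (SRT, d).
ENV_VARIABLES = (
    "influent_BOD",
    "effluent_BOD",
    "influent_NH3",
    "effluent_NH3",
    "effluent_NO2",
    "effluent_NO3",
    "NH3_removal_eff",
    "DO",
    "temperature",
    "SVI",
    "MLSS",
    "SRT",
)

#: T-RF size window (bp) retained by default: fragments shorter than 50 bp or
#: longer than 500 bp are discarded to avoid primer peaks and sizing
#: uncertainty at the extremes of the size standard.
MIN_TRF_BP = 50
MAX_TRF_BP = 500


@dataclass
class CommunityProfile:
    """Relative-abundance fingerprint of one sample.

    ``abundances`` maps integer T-RF bin labels (fragment length, bp) to
    relative abundance fractions.  ``removed_mass`` records the total relative
    abundance discarded by the noise filter, so kept + removed mass stays 1.
    """

    sample_id: str
    time_days: float
    abundances: dict[int, float] = field(default_factory=dict)
    removed_mass: float = 0.0

    def total(self) -> float:
        return float(sum(self.abundances.values()))

    def as_vector(self, bins: list[int]) -> np.ndarray:
        """Abundances over an explicit bin list, 0.0 for absent bins."""
        return np.array([self.abundances.get(b, 0.0) for b in bins], dtype=float)

    def validate(self) -> None:
        if not self.abundances:
            raise ValueError(f"sample {self.sample_id!r}: empty profile")
        if abs(self.total() - 1.0) > 1e-9 and self.removed_mass == 0.0:
            raise ValueError(
                f"sample {self.sample_id!r}: abundances sum to {self.total():.12f}, not 1"
            )
        for b in self.abundances:
            if not (MIN_TRF_BP <= b <= MAX_TRF_BP):
                raise ValueError(
                    f"sample {self.sample_id!r}: bin {b} outside [{MIN_TRF_BP}, {MAX_TRF_BP}]"
                )


@dataclass
class ProfileSeries:
    """Time-ordered community profiles over the union of their T-RF bins."""

    profiles: list[CommunityProfile]

    def __post_init__(self) -> None:
        times = [p.time_days for p in self.profiles]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("time_days must be strictly increasing")
        ids = [p.sample_id for p in self.profiles]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate sample_id(s): {dupes}")

    def __len__(self) -> int:
        return len(self.profiles)

    def __iter__(self):
        return iter(self.profiles)

    @property
    def sample_ids(self) -> list[str]:
        return [p.sample_id for p in self.profiles]

    @property
    def times(self) -> np.ndarray:
        return np.array([p.time_days for p in self.profiles], dtype=float)

    @property
    def bin_labels(self) -> list[int]:
        bins: set[int] = set()
        for p in self.profiles:
            bins.update(p.abundances)
        return sorted(bins)

    def matrix(self) -> pd.DataFrame:
        """Samples x bins relative-abundance matrix with explicit zeros."""
        bins = self.bin_labels
        data = np.vstack([p.as_vector(bins) for p in self.profiles])
        return pd.DataFrame(data, index=self.sample_ids, columns=bins)

    @classmethod
    def from_matrix(cls, frame: pd.DataFrame, times) -> "ProfileSeries":
        """Build a series from a samples x bins frame and per-sample times."""
        times = np.asarray(times, dtype=float)
        if len(times) != len(frame):
            raise ValueError("times length must match number of rows")
        order = np.argsort(times)
        profiles = []
        for i in order:
            row = frame.iloc[int(i)]
            abund = {int(b): float(v) for b, v in row.items() if v > 0}
            profiles.append(
                CommunityProfile(str(frame.index[int(i)]), float(times[i]), abund)
            )
        return cls(profiles)

    def to_tsv(self, path) -> None:
        m = self.matrix()
        m.insert(0, "time_days", self.times)
        m.to_csv(path, sep="\t", index_label="sample_id")

    @classmethod
    def read_tsv(cls, path) -> "ProfileSeries":
        m = pd.read_csv(path, sep="\t", index_col="sample_id")
        times = m.pop("time_days").to_numpy()
        m.columns = [int(c) for c in m.columns]
        return cls.from_matrix(m, times)


def validate_env_table(env: pd.DataFrame) -> pd.DataFrame:
    """Check physical ranges of an env table; NaN is allowed (flagged, not imputed)."""
    if "sample_id" not in env.columns:
        raise ValueError("env table missing required column 'sample_id'")
    conc = [
        v
        for v in ENV_VARIABLES
        if v in env.columns and v not in ("temperature", "NH3_removal_eff")
    ]
    for v in conc:
        bad = env.index[env[v] < 0]
        if len(bad):
            raise ValueError(f"env variable {v!r} negative at rows {list(bad)}")
    if "NH3_removal_eff" in env.columns:
        x = env["NH3_removal_eff"]
        bad = env.index[(x < 0) | (x > 100)]
        if len(bad):
            raise ValueError(f"NH3_removal_eff outside [0, 100] at rows {list(bad)}")
    return env


def read_env_table(path) -> pd.DataFrame:
    """Read an environmental covariate CSV (sample_id, time_days, variables)."""
    env = pd.read_csv(path)
    return validate_env_table(env)
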