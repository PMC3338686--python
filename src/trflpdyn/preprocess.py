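"""Turn raw fragment-analysis peak tables into aligned relative-abundance profiles.

The preprocessing chain mirrors standard T-RFLP practice:

1. :func:`filter_size_window` — keep fragments within the 50–500 bp sizing
   window (inclusive boundaries; only strict violations are excluded).
2. :func:`bin_trfs` — cluster fragment lengths across samples by
   single-linkage with a 1 bp tolerance (typical capillary sizing precision)
   and label each bin with the rounded area-weighted mean length.
3. :func:`relative_abundance` — divide each peak area by the total area of
   its sample.
4. :func:`filter_noise` — discard bins with relative abundance strictly below
   2% as background noise and (by default) renormalize the remainder so the
   profile is again a composition.
5. :func:`assemble_series` — align profiles and covariates into a
   time-ordered series over the union of bins.

A peak table is a :class:`pandas.DataFrame` with columns ``sample_id``,
``time_days``, ``fragment_length`` (bp) and ``area`` (fluorescence units).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .profiles import (
    MAX_TRF_BP,
    MIN_TRF_BP,
    CommunityProfile,
    ProfileSeries,
)

PEAK_COLUMNS = ("sample_id", "time_days", "fragment_length", "area")


def read_peak_table(path) -> pd.DataFrame:
    """Read a peak-table CSV, validating schema and physical ranges.

    Required columns: sample_id, time_days, fragment_length, area (extra
    columns are ignored).  Malformed rows are reported with their CSV line
    numbers (header = line 1).
    """
    table = pd.read_csv(path)
    missing = [c for c in PEAK_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"peak table missing required column(s): {', '.join(missing)}")
    table = table.loc[:, list(PEAK_COLUMNS)].copy()
    bad_lines: list[str] = []
    for col in ("time_days", "fragment_length", "area"):
        coerced = pd.to_numeric(table[col], errors="coerce")
        for i in table.index[coerced.isna() & table[col].notna()]:
            bad_lines.append(f"line {i + 2}: non-numeric {col} ({table.at[i, col]!r})")
        table[col] = coerced
    for i in table.index[table["area"] < 0]:
        bad_lines.append(f"line {i + 2}: negative area ({table.at[i, 'area']})")
    for i in table.index[table["fragment_length"] <= 0]:
        bad_lines.append(f"line {i + 2}: non-positive fragment_length")
    if bad_lines:
        raise ValueError("malformed peak table rows: " + "; ".join(bad_lines))
    return validate_peak_table(table)


def validate_peak_table(peaks: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in PEAK_COLUMNS if c not in peaks.columns]
    if missing:
        raise ValueError(f"peak table missing required column(s): {', '.join(missing)}")
    if (peaks["area"] < 0).any():
        raise ValueError("peak table contains negative areas")
    if (peaks["fragment_length"] <= 0).any():
        raise ValueError("peak table contains non-positive fragment lengths")
    return peaks


def filter_size_window(
    peaks: pd.DataFrame, min_bp: float = MIN_TRF_BP, max_bp: float = MAX_TRF_BP
) -> pd.DataFrame:
    """Keep peaks with min_bp <= fragment_length <= max_bp (boundaries inclusive)."""
    if min_bp >= max_bp:
        raise ValueError(f"min_bp ({min_bp}) must be < max_bp ({max_bp})")
    keep = (peaks["fragment_length"] >= min_bp) & (peaks["fragment_length"] <= max_bp)
    return peaks.loc[keep].reset_index(drop=True)


def bin_trfs(peaks: pd.DataFrame, tolerance_bp: float = 1.0) -> pd.DataFrame:
    """Cluster fragment lengths across samples into integer-labelled T-RF bins.

    Single-linkage in one dimension: sorted lengths are split wherever the gap
    between neighbours exceeds ``tolerance_bp`` (so chains of closely spaced
    peaks merge).  Each cluster is labelled with the rounded area-weighted mean
    length; within a sample, areas of peaks falling in one cluster are summed.
    """
    if peaks.empty:
        return peaks.copy()
    work = peaks.sort_values("fragment_length", kind="stable").reset_index(drop=True)
    lengths = work["fragment_length"].to_numpy(dtype=float)
    gaps = np.diff(lengths)
    cluster = np.concatenate([[0], np.cumsum(gaps > tolerance_bp)])
    work["_cluster"] = cluster

    def _label(g: pd.DataFrame) -> int:
        w = g["area"].to_numpy(dtype=float)
        x = g["fragment_length"].to_numpy(dtype=float)
        mean = x.mean() if w.sum() == 0 else float(np.average(x, weights=w))
        return int(round(mean))

    labels = {c: _label(g) for c, g in work.groupby("_cluster")}
    work["fragment_length"] = work["_cluster"].map(labels)
    out = (
        work.groupby(["sample_id", "time_days", "fragment_length"], as_index=False)[
            "area"
        ]
        .sum()
        .loc[:, list(PEAK_COLUMNS)]
    )
    return out.reset_index(drop=True)


def relative_abundance(peaks: pd.DataFrame) -> list[CommunityProfile]:
    """Per-sample relative abundances: area(bin) / total area of the sample."""
    profiles = []
    for (sid, t), g in peaks.groupby(["sample_id", "time_days"], sort=False):
        total = float(g["area"].sum())
        if total <= 0:
            raise ValueError(f"sample {sid!r}: zero total peak area")
        abund = {
            int(b): float(a) / total
            for b, a in zip(g["fragment_length"], g["area"])
            if a > 0
        }
        profiles.append(CommunityProfile(str(sid), float(t), abund))
    return profiles


def filter_noise(
    profile: CommunityProfile, floor: float = 0.02, renormalize: bool = True
) -> CommunityProfile:
    """Drop bins with relative abundance strictly below ``floor`` (background noise).

    Bins exactly at the floor are retained ("below 2%" is a strict
    inequality).  With ``renormalize`` the surviving abundances are rescaled
    to sum to 1 so the profile remains a composition (required downstream for
    Pearson similarity and correspondence analysis); without it the raw ratios
    are kept.  The removed mass is recorded on the returned profile either way.
    """
    kept = {b: a for b, a in profile.abundances.items() if a >= floor}
    removed = sum(a for b, a in profile.abundances.items() if b not in kept)
    if not kept:
        raise ValueError(
            f"sample {profile.sample_id!r}: all T-RFs below the {floor:.0%} noise "
            "floor (no community signal)"
        )
    if renormalize:
        s = sum(kept.values())
        kept = {b: a / s for b, a in kept.items()}
    return CommunityProfile(
        profile.sample_id, profile.time_days, kept, removed_mass=float(removed)
    )


def assemble_series(
    profiles: list[CommunityProfile], env: pd.DataFrame | None = None
) -> tuple[ProfileSeries, pd.DataFrame | None]:
    """Sort profiles by time, union their bins, and align env rows to the same order."""
    ordered = sorted(profiles, key=lambda p: p.time_days)
    series = ProfileSeries(ordered)
    if env is None:
        return series, None
    env_ids = set(env["sample_id"].astype(str))
    prof_ids = set(series.sample_ids)
    only_prof = sorted(prof_ids - env_ids)
    only_env = sorted(env_ids - prof_ids)
    if only_prof or only_env:
        parts = []
        if only_prof:
            parts.append(f"samples missing from env table: {only_prof}")
        if only_env:
            parts.append(f"env rows without profiles: {only_env}")
        raise ValueError("; ".join(parts))
    aligned = (
        env.assign(sample_id=env["sample_id"].astype(str))
        .set_index("sample_id")
        .loc[series.sample_ids]
        .reset_index()
    )
    return series, aligned


def preprocess_peaks(
    peaks: pd.DataFrame,
    env: pd.DataFrame | None = None,
    *,
    min_bp: float = MIN_TRF_BP,
    max_bp: float = MAX_TRF_BP,
    bin_tolerance_bp: float = 1.0,
    noise_floor: float = 0.02,
    renormalize: bool = True,
) -> tuple[ProfileSeries, pd.DataFrame | None]:
    """Full chain: size window -> binning -> relative abundance -> noise filter -> series."""
    validate_peak_table(peaks)
    windowed = filter_size_window(peaks, min_bp, max_bp)
    binned = bin_trfs(windowed, bin_tolerance_bp)
    profiles = relative_abundance(binned)
    filtered = [filter_noise(p, noise_floor, renormalize) for p in profiles]
    return assemble_series(filtered, env)
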