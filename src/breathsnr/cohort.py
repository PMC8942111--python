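"""Cohort-level analysis: SNR vs the 1-10 health-scale score.

Per-subject session SNRs are averaged (in dB) into one value per subject,
grouped by occupied health-scale value, min-max normalized for comparison,
and tested for a positive monotone association by Spearman rank correlation
with a one-sided permutation p-value.  The health scale is ordinal, hence
rank correlation; averaging is done in dB because the normalized group
curve is a dB-derived quantity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientDataError, InvalidConfigurationError, UndefinedResultError
from .snr import SnrResult


@dataclass
class CohortTable:
    """One row per subject: id, group, health scale, mean session SNR (dB)."""

    df: pd.DataFrame

    REQUIRED = ("subject_id", "group", "health_scale", "mean_snr_db")

    def __post_init__(self) -> None:
        missing = set(self.REQUIRED) - set(self.df.columns)
        if missing:
            raise InvalidConfigurationError(f"missing columns: {sorted(missing)}")
        if self.df["subject_id"].duplicated().any():
            raise InvalidConfigurationError("one row per subject required")

    def __len__(self) -> int:
        return len(self.df)


@dataclass(frozen=True)
class CorrelationResult:
    rho: float
    p_value: float
    n: int
    method: str = "spearman-permutation"


def aggregate_subject(results: list[SnrResult],
                      drop_low_confidence: bool = True) -> float:
    """Arithmetic mean SNR in dB across a subject's channels/sessions.

    Low-confidence results are excluded when any confident one remains.
    """
    if not results:
        raise InsufficientDataError("no SNR results for this subject")
    if drop_low_confidence:
        kept = [r for r in results if not r.low_confidence]
        if kept:
            results = kept
    return float(np.mean([r.snr_db for r in results]))


def build_table(rows: list[dict]) -> CohortTable:
    """Assemble a CohortTable from per-subject dicts."""
    return CohortTable(pd.DataFrame(rows))


def group_normalize(table: CohortTable, policy: str = "error") -> pd.DataFrame:
    """Group-average SNR per occupied health-scale value, min-max normalized.

    Returns a frame (health_scale, mean_snr_db, normalized) sorted by scale;
    unoccupied scale values are omitted, not interpolated.  When every group
    mean is equal the normalization is undefined: ``policy='error'`` raises,
    ``policy='half'`` reports 0.5 for every group.
    """
    df = table.df
    if df["health_scale"].nunique() < 2:
        raise UndefinedResultError(
            "normalization needs >= 2 distinct health-scale values")
    means = (df.groupby("health_scale")["mean_snr_db"].mean()
             .rename("mean_snr_db").reset_index()
             .sort_values("health_scale", ignore_index=True))
    lo, hi = means["mean_snr_db"].min(), means["mean_snr_db"].max()
    if hi == lo:
        if policy == "half":
            means["normalized"] = 0.5
            return means
        raise UndefinedResultError(
            "all group means equal; min-max normalization undefined")
    means["normalized"] = (means["mean_snr_db"] - lo) / (hi - lo)
    return means


def correlation_test(table: CohortTable, n_permutations: int = 999,
                     seed: int | None = None) -> CorrelationResult:
    """Spearman correlation of health scale vs mean SNR, permutation-tested.

    The p-value is one-sided for positive association: the fraction of
    ``n_permutations`` health-scale shuffles whose rank correlation is at
    least the observed one, with the +1 add-one correction, so p is in
    [1/(n+1), 1] and reproducible under a fixed seed.  Ties receive average
    ranks.
    """
    df = table.df
    if len(df) < 5:
        raise InsufficientDataError("correlation needs >= 5 subjects")
    if df["health_scale"].nunique() < 2:
        raise InsufficientDataError("correlation needs >= 2 distinct scales")
    snr = df["mean_snr_db"].to_numpy(dtype=np.float64)
    scale = df["health_scale"].to_numpy(dtype=np.float64)
    if np.ptp(snr) == 0.0:
        raise UndefinedResultError(
            "SNR column is constant; rank correlation undefined")

    rx = stats.rankdata(scale)
    ry = stats.rankdata(snr)
    rx = (rx - rx.mean()) / rx.std()
    ry = (ry - ry.mean()) / ry.std()
    n = len(df)
    rho = float(rx @ ry / n)

    rng = np.random.default_rng(seed)
    # vectorized shuffles: each row an independent permutation of rx
    perm = np.argsort(rng.random((n_permutations, n)), axis=1)
    rho_null = (rx[perm] @ ry) / n
    p = float((1 + np.sum(rho_null >= rho)) / (n_permutations + 1))
    return CorrelationResult(rho=rho, p_value=p, n=n)


def cohort_from_results(results_df: pd.DataFrame,
                        metadata_df: pd.DataFrame,
                        drop_low_confidence: bool = True) -> CohortTable:
    """Join a per-channel results table with subject metadata.

    ``results_df`` follows the results-CSV schema (subject_id, channel,
    snr_db, optionally low_confidence); ``metadata_df`` the cohort metadata
    schema (subject_id, group, health_scale, ...).
    """
    df = results_df.copy()
    if "low_confidence" in df.columns and drop_low_confidence:
        confident = df[~df["low_confidence"].astype(bool)]
        # keep low-confidence rows only for subjects with nothing better
        has_conf = set(confident["subject_id"])
        df = pd.concat([confident,
                        df[~df["subject_id"].isin(has_conf)]])
    per_subject = (df.groupby("subject_id")["snr_db"].mean()
                   .rename("mean_snr_db").reset_index())
    merged = per_subject.merge(
        metadata_df[["subject_id", "group", "health_scale"]],
        on="subject_id", how="inner")
    return CohortTable(merged)


def summarize(table: CohortTable, n_permutations: int = 999,
              seed: int | None = None) -> dict:
    """JSON-ready cohort summary: correlation plus normalized group means."""
    corr = correlation_test(table, n_permutations=n_permutations, seed=seed)
    norm = group_normalize(table)
    copd = table.df[table.df["group"] == "copd"]
    out = {
        "n_subjects": len(table),
        "rho": corr.rho,
        "p_value": corr.p_value,
        "method": corr.method,
        "normalized_group_means": {
            int(r.health_scale): float(r.normalized)
            for r in norm.itertuples()
        },
    }
    if len(copd):
        out["copd_mean_health_scale"] = float(copd["health_scale"].mean())
    return out
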