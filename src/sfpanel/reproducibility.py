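"""Reproducibility of the saliva panel: CV and within- vs between-subject variance.

Two study designs feed this module: a *repeat* design (one woman sampled
on several days) and a *diversity* design (several women sampled once).
Per-target coefficients of variation across the repeat series quantify
method reproducibility; the within-vs-between comparison asks whether
the variability between women exceeds the day-to-day variability of one
woman — the property that makes the panel a per-woman "fingerprint".

The comparison statistic is the variance ratio between-series /
within-series.  Because relative-expression values are not assumed
normal, the default reference distribution is a permutation one (values
shuffled between the two series); a parametric F-test is available as
an option.  CVs are computed on the relative-expression scale by
default, switchable to the ΔCt scale.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .quantify import PANEL_TARGETS

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CVReport:
    """Coefficient of variation of one target over a sample series."""

    target: str
    n_samples: int
    mean_rel_expr: float
    sd_rel_expr: float
    cv: float  # sd / mean; NaN when undefined (n < 2 or mean <= 0)


@dataclass(frozen=True)
class VarianceComparisonResults:
    """Within- vs between-subject variance comparison for one endpoint."""

    endpoint: str
    n_within: int
    n_between: int
    within_variance: float
    between_variance: float
    statistic: float  # between / within variance ratio
    p_value: float
    method: str  # "permutation" | "f-test" | "degenerate"
    n_permutations: int | None = None
    seed: int | None = None

    def summary(self) -> str:
        return "\n".join(
            [
                f"Within- vs between-subject variance — endpoint: {self.endpoint}",
                f"  n (within-series / between-series): {self.n_within} / {self.n_between}",
                f"  within variance:   {self.within_variance:.6g}",
                f"  between variance:  {self.between_variance:.6g}",
                f"  variance ratio:    {self.statistic:.6g}",
                f"  one-sided p:       {self.p_value:.4g}  ({self.method})",
            ]
        )


@dataclass(frozen=True)
class VarianceComponents:
    """Method-of-moments variance components on the ΔCt scale."""

    target: str
    sigma_between: float
    sigma_within: float
    n_subjects: int
    n_days: int


def cv(values: Sequence[float]) -> tuple[float, float, float]:
    """Return (mean, sample SD, CV) of a series; CV is NaN when undefined."""
    arr = np.asarray(list(values), dtype=float)
    arr = arr[~np.isnan(arr)]
    if arr.size == 0:
        return (math.nan, math.nan, math.nan)
    mean = float(arr.mean())
    if arr.size < 2:
        return (mean, math.nan, math.nan)
    sd = float(arr.std(ddof=1))
    if mean <= 0:
        logger.warning("CV undefined: non-positive mean %g", mean)
        return (mean, sd, math.nan)
    return (mean, sd, sd / mean)


def cv_per_target(
    profiles: pd.DataFrame,
    targets: Sequence[str] = PANEL_TARGETS,
    scale: str = "rel_expr",
    include_composite: bool = True,
) -> list[CVReport]:
    """CV of each target (and the composite) across the rows of a profile table.

    Intended for a repeat-design table: the samples of one subject over
    days.  ``scale`` selects relative expression (default) or ΔCt.
    """
    if scale not in {"rel_expr", "delta_ct"}:
        raise ValueError(f"unknown scale {scale!r}")
    columns = [(t, f"{scale}_{t}") for t in targets]
    if include_composite and "composite_score" in profiles.columns:
        columns.append(("composite", "composite_score"))
    reports = []
    for name, col in columns:
        if col not in profiles.columns:
            raise ValueError(f"profiles table has no column {col!r}")
        series = profiles[col].to_numpy(dtype=float)
        n = int(np.sum(~np.isnan(series)))
        mean, sd, c = cv(series)
        reports.append(CVReport(name, n, mean, sd, c))
    return reports


def cv_reports_to_frame(reports: Sequence[CVReport]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "target": [r.target for r in reports],
            "n_samples": [r.n_samples for r in reports],
            "mean_rel_expr": [r.mean_rel_expr for r in reports],
            "sd_rel_expr": [r.sd_rel_expr for r in reports],
            "cv": [r.cv for r in reports],
        }
    )


class WithinBetweenComparison:
    """Model object comparing a repeat series to a diversity series.

    Parameters
    ----------
    within_values
        Endpoint values of one subject over D days (D >= 2).
    between_values
        Endpoint values of W different subjects, one day each (W >= 2).
    """

    def __init__(self, within_values, between_values, endpoint: str = "composite") -> None:
        w = np.asarray(within_values, dtype=float)
        b = np.asarray(between_values, dtype=float)
        w, b = w[~np.isnan(w)], b[~np.isnan(b)]
        if w.size < 2 or b.size < 2:
            raise ValueError("both series need >= 2 defined values")
        self.within = w
        self.between = b
        self.endpoint = endpoint

    @classmethod
    def from_profiles(
        cls,
        repro_profiles: pd.DataFrame,
        diversity_profiles: pd.DataFrame,
        endpoint: str = "composite",
    ) -> "WithinBetweenComparison":
        col = "composite_score" if endpoint == "composite" else f"rel_expr_{endpoint}"
        for df in (repro_profiles, diversity_profiles):
            if col not in df.columns:
                raise ValueError(f"profiles table has no column {col!r}")
        return cls(
            repro_profiles[col].to_numpy(),
            diversity_profiles[col].to_numpy(),
            endpoint,
        )

    def fit(
        self,
        method: str = "permutation",
        n_permutations: int = 9999,
        seed: int | None = None,
    ) -> VarianceComparisonResults:
        """One-sided test of between-variance > within-variance."""
        w, b = self.within, self.between
        var_w = float(w.var(ddof=1))
        var_b = float(b.var(ddof=1))
        pooled = np.concatenate([b, w])

        if np.allclose(pooled, pooled[0]):
            # Both series are the same constant: no variance anywhere.
            return VarianceComparisonResults(
                self.endpoint, w.size, b.size, var_w, var_b,
                math.nan, 1.0, "degenerate",
            )

        ratio = var_b / var_w if var_w > 0 else math.inf

        if method == "f-test":
            p = float(stats.f.sf(ratio, b.size - 1, w.size - 1)) if var_w > 0 else 0.0
            return VarianceComparisonResults(
                self.endpoint, w.size, b.size, var_w, var_b, ratio, p, "f-test"
            )
        if method != "permutation":
            raise ValueError(f"unknown method {method!r}")
        if n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")

        rng = np.random.default_rng(seed)
        nb = b.size
        order = np.argsort(rng.random((n_permutations, pooled.size)), axis=1)
        perm = pooled[order]
        var_b_perm = perm[:, :nb].var(ddof=1, axis=1)
        var_w_perm = perm[:, nb:].var(ddof=1, axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            null = np.where(var_w_perm > 0, var_b_perm / var_w_perm, np.inf)
        thresh = ratio - 1e-12 * max(1.0, abs(ratio)) if math.isfinite(ratio) else ratio
        hits = int(np.sum(null >= thresh))
        p = (hits + 1) / (n_permutations + 1)
        return VarianceComparisonResults(
            self.endpoint, w.size, b.size, var_w, var_b, ratio, p,
            "permutation", n_permutations, seed,
        )


def compare_within_between(
    repro_profiles: pd.DataFrame,
    diversity_profiles: pd.DataFrame,
    endpoints: Sequence[str] | None = None,
    method: str = "permutation",
    n_permutations: int = 9999,
    seed: int | None = None,
) -> pd.DataFrame:
    """Within- vs between-subject comparison per target and on the composite.

    Returns one row per endpoint with variances, the ratio statistic and
    its one-sided p-value.  Per-endpoint permutation streams are split
    off the one seed.
    """
    if endpoints is None:
        endpoints = list(PANEL_TARGETS) + ["composite"]
    children = np.random.SeedSequence(seed).spawn(len(endpoints))
    rows = []
    for endpoint, child in zip(endpoints, children):
        sub_seed = int(child.generate_state(1)[0] % (2**31))
        model = WithinBetweenComparison.from_profiles(
            repro_profiles, diversity_profiles, endpoint
        )
        rows.append(model.fit(method, n_permutations, sub_seed))
    return pd.DataFrame(
        {
            "endpoint": [r.endpoint for r in rows],
            "n_within": [r.n_within for r in rows],
            "n_between": [r.n_between for r in rows],
            "within_variance": [r.within_variance for r in rows],
            "between_variance": [r.between_variance for r in rows],
            "statistic": [r.statistic for r in rows],
            "p_value": [r.p_value for r in rows],
            "method": [r.method for r in rows],
        }
    )


def estimate_variance_components(
    profiles: pd.DataFrame,
    target: str,
    scale: str = "delta_ct",
) -> VarianceComponents:
    """Method-of-moments variance components from a subjects x days design.

    Expects a profiles table with ``subject_id`` and ``collection_day``
    and a balanced design (every subject measured on the same number of
    days).  The within-subject variance is the mean of the per-subject
    sample variances across days; the between-subject variance corrects
    the variance of subject means for the sampling noise of those means:

        sigma_between^2 = Var(subject means) - sigma_within^2 / D

    clipped at zero.  On the ΔCt scale (default) these estimate the
    generator's ``sigma_between`` and ``sigma_within`` directly (plus a
    small replicate-noise contribution to the within term).
    """
    col = f"{scale}_{target}"
    if col not in profiles.columns:
        raise ValueError(f"profiles table has no column {col!r}")
    wide = profiles.pivot_table(
        index="subject_id", columns="collection_day", values=col
    )
    if wide.shape[1] < 2:
        raise ValueError("variance components need >= 2 collection days")
    if wide.isna().any().any():
        raise ValueError("variance components require a balanced subjects x days design")
    d = wide.shape[1]
    within = float(wide.var(axis=1, ddof=1).mean())
    subject_means = wide.mean(axis=1)
    between = max(float(subject_means.var(ddof=1)) - within / d, 0.0)
    return VarianceComponents(
        target=target,
        sigma_between=math.sqrt(between),
        sigma_within=math.sqrt(within),
        n_subjects=wide.shape[0],
        n_days=d,
    )
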