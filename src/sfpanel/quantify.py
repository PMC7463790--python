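"""Comparative-Ct quantification of the saliva splicing-factor panel.

Real-time PCR reports, for each well, the cycle number Ct at which the
amplification signal crosses the detection threshold; each extra cycle
corresponds to a two-fold dilution of the starting template, so lower Ct
means more transcript.  Quantification is relative to an endogenous
control gene measured in the same sample (here PPIA, which is abundant
and stable in cell-free saliva):

    dCt_g   = mean Ct of target g over detected replicates
              - mean Ct of the normalizer over detected replicates
    rel_g   = 2 ** (-dCt_g)

``rel_g`` is a dimensionless abundance relative to PPIA under perfect
doubling efficiency.  The panel endpoint is the composite score: the sum
of the relative expression values of the seven splicing-factor targets
(HNRNPA1, HNRNPA2B1, HNRNPA3, HNRNPK, the HNRNPK exon-8-inclusion
isoform, PTBP1 and SRSF6).  Summing on the ΔCt scale instead is exposed
as an option (``score_scale="delta_ct"``).

Undetected wells are encoded as missing values (NaN / blank cells),
never as a sentinel cycle number.  A sample whose normalizer is entirely
undetected cannot be quantified at all and is dropped with a logged
warning (or raises, if requested).
"""

from __future__ import annotations

import logging
import math
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: The seven-gene splicing-factor panel measured in cell-free saliva.
PANEL_TARGETS: tuple[str, ...] = (
    "HNRNPA1",
    "HNRNPA2B1",
    "HNRNPA3",
    "HNRNPK",
    "HNRNPK_ex8",
    "PTBP1",
    "SRSF6",
)

#: Endogenous control used for comparative-Ct normalisation.
DEFAULT_NORMALIZER = "PPIA"

#: Columns a long-format Ct table must provide.
CT_REQUIRED_COLUMNS = ("sample_id", "target", "replicate", "ct")

#: Optional per-sample annotation columns carried through to profiles.
CT_META_COLUMNS = ("subject_id", "group", "age", "collection_day")


class UndetectedNormalizerError(ValueError):
    """The normalizer gene was not detected, so nothing can be quantified."""


def aggregate_replicates(cts: Iterable[float]) -> tuple[float, int]:
    """Aggregate technical replicate Ct values for one sample/target.

    Parameters
    ----------
    cts
        Replicate Ct readings in cycles; undetected wells as NaN.

    Returns
    -------
    (mean_ct, n_detected)
        Arithmetic mean of the detected replicates and their count.
        With zero detected replicates the target is flagged undetected:
        ``(nan, 0)``.
    """
    arr = np.asarray(list(cts), dtype=float)
    detected = arr[~np.isnan(arr)]
    if detected.size and np.any(detected <= 0):
        raise ValueError("detected Ct values must be positive cycle numbers")
    if detected.size == 0:
        return (math.nan, 0)
    return (float(detected.mean()), int(detected.size))


def delta_ct(ct_target: float, ct_normalizer: float) -> float:
    """Ct of the target minus Ct of the normalizer, in cycles."""
    if np.isnan(ct_normalizer):
        raise UndetectedNormalizerError(
            "normalizer Ct is undetected; the sample cannot be quantified"
        )
    if np.isnan(ct_target):
        raise ValueError("target Ct is undetected; no delta-Ct is defined")
    return float(ct_target) - float(ct_normalizer)


def relative_expression(dct):
    """Relative expression ``2**(-dCt)`` under perfect doubling.

    Accepts scalars or arrays; strictly decreasing in ΔCt and equal to 1
    at ΔCt = 0 (target as abundant as the normalizer).
    """
    return 2.0 ** (-np.asarray(dct, dtype=float))


def composite_score(
    rel_expr: Mapping[str, float] | Sequence[float],
    targets: Sequence[str] = PANEL_TARGETS,
    missing_policy: str = "strict",
) -> float:
    """Composite panel score: summed relative expression over the panel.

    Parameters
    ----------
    rel_expr
        Per-target relative expression, either a mapping keyed by target
        name or a sequence aligned with ``targets``; NaN = undetected.
    missing_policy
        ``"strict"`` (default): the score is defined only when every
        panel target is detected; otherwise NaN is returned and the
        dropout is logged.  ``"rescale"``: the sum over detected targets
        is rescaled by ``len(targets) / n_detected``.

    Raises
    ------
    ValueError
        If no target at all is detected, or the policy is unknown.
    """
    if isinstance(rel_expr, Mapping):
        values = np.array([rel_expr.get(t, math.nan) for t in targets], dtype=float)
    else:
        values = np.asarray(list(rel_expr), dtype=float)
        if values.size != len(targets):
            raise ValueError(
                f"expected {len(targets)} relative-expression values, got {values.size}"
            )
    detected = ~np.isnan(values)
    n_det = int(detected.sum())
    if n_det == 0:
        raise ValueError("composite score undefined: no panel target detected")
    if missing_policy == "strict":
        if n_det < len(targets):
            logger.warning(
                "composite score undefined under strict policy: %d/%d targets detected",
                n_det,
                len(targets),
            )
            return math.nan
        return float(values.sum())
    if missing_policy == "rescale":
        return float(values[detected].sum() * len(targets) / n_det)
    raise ValueError(f"unknown missing_policy {missing_policy!r}")


def read_ct_csv(path) -> pd.DataFrame:
    """Read a long-format Ct CSV (blank / ND / Undetermined cells = undetected)."""
    df = pd.read_csv(
        path,
        na_values=["", "ND", "NA", "undetected", "Undetermined"],
        keep_default_na=True,
    )
    missing = [c for c in CT_REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"Ct table is missing required columns: {missing}")
    df["ct"] = pd.to_numeric(df["ct"], errors="coerce")
    return df


def quantify_profiles(
    ct_table: pd.DataFrame,
    normalizer: str = DEFAULT_NORMALIZER,
    targets: Sequence[str] = PANEL_TARGETS,
    score_scale: str = "rel_expr",
    missing_policy: str = "strict",
    on_missing_normalizer: str = "drop",
) -> pd.DataFrame:
    """Quantify per-sample expression profiles from a long Ct table.

    Replicates are aggregated by averaging detected Ct values per
    (sample, target); ΔCt is taken against the normalizer aggregated the
    same way; relative expression is ``2**(-dCt)``; and the composite
    score sums relative expression (or ΔCt, with
    ``score_scale="delta_ct"``) over the panel targets.

    Parameters
    ----------
    ct_table
        Long table with columns ``sample_id, target, replicate, ct``;
        per-sample annotations (``subject_id, group, age,
        collection_day``) are carried through when present.
    on_missing_normalizer
        ``"drop"`` (default): samples without a detected normalizer are
        excluded with a logged warning; ``"raise"``: fail instead.

    Returns
    -------
    DataFrame
        One row per quantifiable sample with ``delta_ct_<target>`` and
        ``rel_expr_<target>`` columns, ``n_targets_detected`` and
        ``composite_score``.
    """
    missing = [c for c in CT_REQUIRED_COLUMNS if c not in ct_table.columns]
    if missing:
        raise ValueError(f"Ct table is missing required columns: {missing}")
    if normalizer in targets:
        raise ValueError("normalizer must not be one of the panel targets")
    df = ct_table.copy()
    df["ct"] = pd.to_numeric(df["ct"], errors="coerce")
    if np.any(df["ct"].dropna() <= 0):
        raise ValueError("detected Ct values must be positive cycle numbers")

    mean_ct = (
        df.groupby(["sample_id", "target"], sort=False)["ct"]
        .mean()  # NaN wells are skipped: mean over detected replicates
        .unstack("target")
    )
    if normalizer not in mean_ct.columns:
        raise UndetectedNormalizerError(
            f"normalizer {normalizer!r} absent from the Ct table"
        )
    absent = [t for t in targets if t not in mean_ct.columns]
    for t in absent:
        mean_ct[t] = math.nan

    norm_ct = mean_ct[normalizer]
    bad = norm_ct.index[norm_ct.isna()]
    if len(bad):
        if on_missing_normalizer == "raise":
            raise UndetectedNormalizerError(
                f"normalizer undetected for samples: {list(bad)}"
            )
        logger.warning(
            "dropping %d sample(s) with undetected normalizer: %s",
            len(bad),
            list(bad),
        )
        mean_ct = mean_ct.drop(index=bad)
        norm_ct = norm_ct.drop(index=bad)

    out = pd.DataFrame(index=mean_ct.index)
    for t in targets:
        out[f"delta_ct_{t}"] = mean_ct[t] - norm_ct
        out[f"rel_expr_{t}"] = relative_expression(out[f"delta_ct_{t}"])

    rel_cols = [f"rel_expr_{t}" for t in targets]
    out["n_targets_detected"] = out[rel_cols].notna().sum(axis=1)

    basis = out[rel_cols] if score_scale == "rel_expr" else None
    if score_scale == "delta_ct":
        basis = out[[f"delta_ct_{t}" for t in targets]]
    elif score_scale != "rel_expr":
        raise ValueError(f"unknown score_scale {score_scale!r}")

    if missing_policy == "strict":
        score = basis.sum(axis=1, min_count=len(targets))
        n_undef = int(score.isna().sum())
        if n_undef:
            logger.warning(
                "composite score undefined for %d sample(s) under strict policy",
                n_undef,
            )
    elif missing_policy == "rescale":
        score = basis.sum(axis=1, min_count=1) * len(targets) / out["n_targets_detected"]
    else:
        raise ValueError(f"unknown missing_policy {missing_policy!r}")
    out["composite_score"] = score

    meta_cols = [c for c in CT_META_COLUMNS if c in df.columns]
    if meta_cols:
        meta = df.drop_duplicates("sample_id").set_index("sample_id")[meta_cols]
        out = meta.reindex(out.index).join(out)
    return out.reset_index().rename(columns={"index": "sample_id"})
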