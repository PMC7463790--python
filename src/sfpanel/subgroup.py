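"""Random-subgroup permutation test for treatment associations.

Within the patient cohort, a treatment sub-group (e.g. the women
receiving the anti-VEGFR antibody avastin) is compared to the remaining
patients on the composite panel score.  The observed statistic is the
absolute difference between the sub-group mean and the remainder mean;
the null distribution is built by drawing random sub-groups of the same
size uniformly without replacement (default 1000 draws) and the p-value
uses the plus-one estimator (b + 1) / (B + 1), so it can never be zero.
Whenever the number of possible sub-groups C(n, k) is small (<= 10^5 by
default) the full set is enumerated instead and the p-value is exact.

Treatment sub-groups are defined by case-insensitive substring match on
the free-text treatment field of the clinical metadata.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from math import comb
from typing import Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .metadata import DEFAULT_TREATMENT_LABELS, PatientRecord, records_to_frame

logger = logging.getLogger(__name__)

_REL_TOL = 1e-12


@dataclass(frozen=True)
class PermutationResult:
    """Result of one random-subgroup permutation test."""

    label: str
    n_subgroup: int
    n_total: int
    observed_statistic: float
    n_draws: int  # Monte-Carlo draws, or enumerated sub-groups
    p_value: float
    method: str  # "monte-carlo" | "exhaustive"
    seed: int | None = None

    def summary(self) -> str:
        return "\n".join(
            [
                f"Subgroup permutation test — label: {self.label}",
                f"  subgroup / total:   {self.n_subgroup} / {self.n_total}",
                f"  |mean difference|:  {self.observed_statistic:.6g}",
                f"  draws:              {self.n_draws} ({self.method})",
                f"  p-value:            {self.p_value:.4g}",
            ]
        )


class SubgroupPermutationTest:
    """Model object: is a labelled sub-group's mean score unusual?

    Parameters
    ----------
    scores
        Composite score (or another endpoint) per patient.
    in_subgroup
        Boolean mask selecting the labelled sub-group; must be neither
        empty nor the whole cohort.
    """

    def __init__(self, scores, in_subgroup, label: str = "subgroup") -> None:
        scores = np.asarray(scores, dtype=float)
        mask = np.asarray(in_subgroup, dtype=bool)
        if scores.shape != mask.shape:
            raise ValueError("scores and subgroup mask must be the same length")
        keep = ~np.isnan(scores)
        n_dropped = int((~keep).sum())
        if n_dropped:
            logger.info("dropping %d patient(s) with undefined score", n_dropped)
        scores, mask = scores[keep], mask[keep]
        k = int(mask.sum())
        if k < 1 or k >= scores.size:
            raise ValueError(
                f"subgroup must be non-empty and proper (got {k} of {scores.size})"
            )
        self.scores = scores
        self.mask = mask
        self.label = label

    @classmethod
    def from_treatment_label(
        cls,
        profiles: pd.DataFrame,
        metadata: pd.DataFrame | Sequence[PatientRecord],
        label: str,
    ) -> "SubgroupPermutationTest":
        """Join profiles to metadata on subject/patient id and mask by treatment.

        Only samples from the patient group are used when a ``group``
        column is present.  The sub-group is every patient whose
        free-text treatment contains ``label`` (case-insensitive).
        """
        if not isinstance(metadata, pd.DataFrame):
            metadata = records_to_frame(metadata)
        patients = profiles
        if "group" in profiles.columns:
            patients = profiles[profiles["group"] == "patient"]
        key = "subject_id" if "subject_id" in patients.columns else "sample_id"
        merged = patients.merge(
            metadata[["patient_id", "treatment"]],
            left_on=key,
            right_on="patient_id",
            how="inner",
        )
        if merged.empty:
            raise ValueError("no profile rows matched the metadata patient ids")
        mask = merged["treatment"].str.lower().str.contains(label.strip().lower(), regex=False)
        return cls(merged["composite_score"].to_numpy(), mask.to_numpy(), label)

    def fit(
        self,
        n_permutations: int = 1000,
        seed: int | None = None,
        exhaustive_limit: int = 100_000,
    ) -> PermutationResult:
        """Run the test and return a :class:`PermutationResult`."""
        if n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        scores, mask = self.scores, self.mask
        n, k = scores.size, int(mask.sum())
        total_sum = scores.sum()

        def stat(sub_sum: np.ndarray | float):
            return np.abs(sub_sum / k - (total_sum - sub_sum) / (n - k))

        observed = float(stat(scores[mask].sum()))
        thresh = observed - _REL_TOL * max(1.0, observed)

        n_combos = comb(n, k)
        if n_combos <= exhaustive_limit:
            hits = 0
            for idx in itertools.combinations(range(n), k):
                if stat(scores[list(idx)].sum()) >= thresh:
                    hits += 1
            return PermutationResult(
                self.label, k, n, observed, n_combos, hits / n_combos,
                "exhaustive", seed,
            )

        rng = np.random.default_rng(seed)
        order = np.argsort(rng.random((n_permutations, n)), axis=1)
        sub_sums = scores[order[:, :k]].sum(axis=1)
        hits = int(np.sum(stat(sub_sums) >= thresh))
        p = (hits + 1) / (n_permutations + 1)
        return PermutationResult(
            self.label, k, n, observed, n_permutations, p, "monte-carlo", seed
        )


def subgroup_permutation_test(
    profiles: pd.DataFrame,
    metadata: pd.DataFrame | Sequence[PatientRecord],
    label: str,
    n_permutations: int = 1000,
    seed: int | None = None,
    exhaustive_limit: int = 100_000,
) -> PermutationResult:
    """Functional wrapper over :class:`SubgroupPermutationTest`."""
    model = SubgroupPermutationTest.from_treatment_label(profiles, metadata, label)
    return model.fit(n_permutations, seed, exhaustive_limit)


def scan_treatment_labels(
    profiles: pd.DataFrame,
    metadata: pd.DataFrame | Sequence[PatientRecord],
    labels: Sequence[str] = DEFAULT_TREATMENT_LABELS,
    n_permutations: int = 1000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Test every canonical treatment label; report raw and Holm-adjusted p.

    Labels whose sub-group is empty or covers the whole cohort are
    skipped with a log entry.  Per-label permutation streams are split
    off the one seed.
    """
    children = np.random.SeedSequence(seed).spawn(len(labels))
    rows: list[PermutationResult] = []
    for label, child in zip(labels, children):
        sub_seed = int(child.generate_state(1)[0] % (2**31))
        try:
            rows.append(
                subgroup_permutation_test(
                    profiles, metadata, label, n_permutations, sub_seed
                )
            )
        except ValueError as exc:
            logger.info("skipping label %r: %s", label, exc)
    if not rows:
        raise ValueError("no testable treatment label")
    table = pd.DataFrame(
        {
            "label": [r.label for r in rows],
            "n_subgroup": [r.n_subgroup for r in rows],
            "n_total": [r.n_total for r in rows],
            "observed_statistic": [r.observed_statistic for r in rows],
            "n_draws": [r.n_draws for r in rows],
            "method": [r.method for r in rows],
            "p_raw": [r.p_value for r in rows],
        }
    )
    table["p_holm"] = multipletests(table["p_raw"], method="holm")[1]
    return table
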