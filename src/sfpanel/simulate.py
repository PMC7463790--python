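"""Synthetic saliva cell-free-RNA datasets.

Everything downstream of sample collection is testable without any real
measurement: this module generates (i) long-format qPCR Ct tables for
the seven-gene splicing-factor panel plus the PPIA normalizer, (ii)
pooled-sample gene-level count tables with a long-tailed abundance
distribution and gene-biotype labels, and (iii) clinical metadata tables
with the same column semantics as the patient-characteristics table
shipped with the package.

The Ct generator draws, for subject *i* in group ``x_i`` (healthy or
patient), collection day *d*, target *g* and technical replicate *r*,

    Ct[g] - Ct[normalizer] = mu_g + beta_g * 1[x_i = patient]
                             + u_{g,i} + e_{g,i,d} + eps_r

with ``u ~ N(0, sigma_between^2)`` a stable per-woman offset (her
cell-free-RNA "fingerprint"), ``e ~ N(0, sigma_within^2)`` day-to-day
drift, and ``eps ~ N(0, sigma_replicate^2)`` well-level technical noise.
One PCR cycle is a two-fold change in abundance, so all effects are in
cycles.  A *negative* ``beta_g`` lowers the patient ΔCt, i.e. raises
expression in patients; the defaults put HNRNPA2B1 slightly down and the
other six targets up in patients.  The normalizer is drawn around a
fixed baseline with replicate noise only — no disease effect.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .metadata import PatientRecord
from .quantify import DEFAULT_NORMALIZER, PANEL_TARGETS

__all__ = [
    "SimulationConfig",
    "CountSimConfig",
    "simulate_ct_dataset",
    "simulate_count_table",
    "simulate_metadata",
    "DEFAULT_MU",
    "DEFAULT_BETA",
    "DEFAULT_AGE_MODEL",
]

#: Baseline ΔCt (cycles above PPIA) per panel target; splicing factors
#: are a few cycles less abundant than the control in cell-free saliva.
DEFAULT_MU: Mapping[str, float] = {
    "HNRNPA1": 3.0,
    "HNRNPA2B1": 2.5,
    "HNRNPA3": 4.0,
    "HNRNPK": 3.0,
    "HNRNPK_ex8": 5.0,
    "PTBP1": 3.5,
    "SRSF6": 4.5,
}

#: Disease effect on ΔCt in cycles (negative = higher expression in
#: patients): HNRNPA2B1 slightly down, the other six up.
DEFAULT_BETA: Mapping[str, float] = {
    "HNRNPA1": -0.7,
    "HNRNPA2B1": 0.4,
    "HNRNPA3": -0.7,
    "HNRNPK": -0.7,
    "HNRNPK_ex8": -0.7,
    "PTBP1": -0.7,
    "SRSF6": -0.7,
}

#: Age-at-collection (mean, SD) in years per group, matching the study
#: cohorts (healthy 40 +/- 12, patients 53 +/- 13).
DEFAULT_AGE_MODEL: Mapping[str, tuple[float, float]] = {
    "healthy": (40.0, 12.0),
    "patient": (53.0, 13.0),
}

#: Gene-biotype classes excluded from the cell-free-RNA count analysis.
EXCLUDED_BIOTYPES: tuple[str, ...] = (
    "IG",
    "TR",
    "artifact",
    "miRNA",
    "Mt_rRNA",
    "Mt_tRNA",
    "ncRNA",
    "piRNA",
    "pre-miRNA",
    "rRNA",
    "ribozyme",
    "sRNA",
    "scRNA",
    "scaRNA",
    "siRNA",
    "snRNA",
    "snoRNA",
    "tRNA",
    "vaultRNA",
)

_KEPT_BIOTYPES = ("protein_coding", "lincRNA", "antisense", "processed_pseudogene")
_KEPT_WEIGHTS = (0.72, 0.12, 0.10, 0.06)


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the Ct-table generator.

    Defaults reproduce the cohort study: 36 healthy women and 31 ER+
    breast-cancer patients, one collection day each, triplicate wells,
    the seven-target panel normalised to PPIA, and disease effects whose
    signs match the reported pattern.  Variance components are in cycles.
    """

    n_healthy: int = 36
    n_patients: int = 31
    n_repeat_days: int = 1
    n_replicates: int = 3
    targets: tuple[str, ...] = PANEL_TARGETS
    normalizer: str = DEFAULT_NORMALIZER
    mu: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_MU))
    beta: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_BETA))
    sigma_between: float = 0.8
    sigma_within: float = 0.25
    sigma_replicate: float = 0.12
    normalizer_baseline_ct: float = 24.0
    age_model: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_AGE_MODEL)
    )
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_healthy < 0 or self.n_patients < 0:
            raise ValueError("cohort sizes must be non-negative")
        if self.n_healthy + self.n_patients < 1:
            raise ValueError("at least one subject is required")
        if self.n_repeat_days < 1 or self.n_replicates < 1:
            raise ValueError("n_repeat_days and n_replicates must be >= 1")
        for name in ("sigma_between", "sigma_within", "sigma_replicate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.normalizer in self.targets:
            raise ValueError("normalizer must not be a panel target")
        missing = [t for t in self.targets if t not in self.mu or t not in self.beta]
        if missing:
            raise ValueError(f"mu/beta missing for targets: {missing}")
        for g, (m, s) in self.age_model.items():
            if s < 0 or m <= 0:
                raise ValueError(f"invalid age model for group {g!r}")


@dataclass(frozen=True)
class CountSimConfig:
    """Conditions for the pooled-sample count-table generator.

    Gene-level means follow a Pareto (power-law) distribution with tail
    index ``tail_shape`` and scale ``tail_scale`` (expected reads), and
    observed counts are Poisson around those means — a long-tailed
    abundance profile in which, at the defaults (20 000 genes), roughly
    1250 genes clear the 49-read presence cutoff before biotype
    exclusion, as in the pooled saliva library the analysis was
    designed for.  A configurable fraction of genes carries a biotype
    from the excluded-class list.
    """

    n_genes: int = 20_000
    n_samples: int = 1
    tail_shape: float = 0.55
    tail_scale: float = 0.3
    excluded_biotype_fraction: float = 0.25
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if not 0.0 <= self.excluded_biotype_fraction <= 1.0:
            raise ValueError("excluded_biotype_fraction must be in [0, 1]")
        if self.tail_shape <= 0 or self.tail_scale <= 0:
            raise ValueError("tail_shape and tail_scale must be > 0")


def simulate_ct_dataset(config: SimulationConfig | None = None) -> pd.DataFrame:
    """Simulate a long-format Ct table under the hierarchical model.

    Returns
    -------
    DataFrame
        Columns ``sample_id, subject_id, group, age, collection_day,
        target, replicate, ct``; one row per well, including normalizer
        wells.  Deterministic under a fixed ``config.seed``.
    """
    config = config or SimulationConfig()
    rng = np.random.default_rng(config.seed)

    n_h, n_p = config.n_healthy, config.n_patients
    n = n_h + n_p
    subjects = np.array(
        [f"H{i + 1:02d}" for i in range(n_h)] + [f"P{i + 1:02d}" for i in range(n_p)]
    )
    groups = np.array(["healthy"] * n_h + ["patient"] * n_p)

    ages = np.empty(n)
    mh, sh = config.age_model.get("healthy", DEFAULT_AGE_MODEL["healthy"])
    mp, sp = config.age_model.get("patient", DEFAULT_AGE_MODEL["patient"])
    ages[:n_h] = rng.normal(mh, sh, n_h)
    ages[n_h:] = rng.normal(mp, sp, n_p)
    ages = np.clip(np.round(ages), 18, 95)

    targets = list(config.targets)
    T, D, R = len(targets), config.n_repeat_days, config.n_replicates
    mu = np.array([config.mu[t] for t in targets])
    beta = np.array([config.beta[t] for t in targets])
    is_patient = (groups == "patient").astype(float)

    u = rng.normal(0.0, config.sigma_between, (n, T))
    e = rng.normal(0.0, config.sigma_within, (n, D, T))
    eps_t = rng.normal(0.0, config.sigma_replicate, (n, D, T, R))
    eps_n = rng.normal(0.0, config.sigma_replicate, (n, D, R))

    dct = (
        mu[None, None, :]
        + beta[None, None, :] * is_patient[:, None, None]
        + u[:, None, :]
        + e
    )  # (n, D, T)
    base = config.normalizer_baseline_ct
    ct_target = base + dct[..., None] + eps_t  # (n, D, T, R)
    ct_norm = base + eps_n  # (n, D, R)

    i, d, t, r = np.unravel_index(np.arange(n * D * T * R), (n, D, T, R))
    frame_t = pd.DataFrame(
        {
            "subject_id": subjects[i],
            "group": groups[i],
            "age": ages[i],
            "collection_day": d + 1,
            "target": np.array(targets)[t],
            "replicate": r + 1,
            "ct": ct_target.ravel(),
        }
    )
    i, d, r = np.unravel_index(np.arange(n * D * R), (n, D, R))
    frame_n = pd.DataFrame(
        {
            "subject_id": subjects[i],
            "group": groups[i],
            "age": ages[i],
            "collection_day": d + 1,
            "target": config.normalizer,
            "replicate": r + 1,
            "ct": ct_norm.ravel(),
        }
    )
    frame = pd.concat([frame_t, frame_n], ignore_index=True)
    frame = frame.sort_values(
        ["subject_id", "collection_day", "target", "replicate"],
        kind="mergesort",
    ).reset_index(drop=True)
    frame.insert(
        0,
        "sample_id",
        frame["subject_id"] + "_d" + frame["collection_day"].astype(str),
    )
    return frame


def simulate_count_table(config: CountSimConfig | None = None) -> pd.DataFrame:
    """Simulate a gene x sample count table with biotype annotation.

    Columns: ``gene_id, symbol, biotype`` then one integer count column
    per sample (``pooled`` for the single-sample default).  Synthetic
    gene identifiers use a ``SYNG``/``SYN`` prefix.
    """
    config = config or CountSimConfig()
    rng = np.random.default_rng(config.seed)
    n = config.n_genes

    lam = config.tail_scale * (1.0 + rng.pareto(config.tail_shape, n))
    counts = rng.poisson(lam[:, None], (n, config.n_samples))

    excluded_draw = rng.choice(np.array(EXCLUDED_BIOTYPES), n)
    kept_draw = rng.choice(np.array(_KEPT_BIOTYPES), n, p=_KEPT_WEIGHTS)
    is_excluded = rng.random(n) < config.excluded_biotype_fraction
    biotype = np.where(is_excluded, excluded_draw, kept_draw)

    table = pd.DataFrame(
        {
            "gene_id": [f"SYNG{i + 1:05d}" for i in range(n)],
            "symbol": [f"SYN{i + 1}" for i in range(n)],
            "biotype": biotype,
        }
    )
    sample_names = (
        ["pooled"]
        if config.n_samples == 1
        else [f"S{j + 1}" for j in range(config.n_samples)]
    )
    for j, name in enumerate(sample_names):
        table[name] = counts[:, j]
    return table


_METASTASIS_SITES = ("Bone", "Liver", "Lung", "Brain", "Adrenal gland")
_TREATMENTS = (
    "Avastin",
    "Avastin and Chemotherapy (cisplatin/gemzar)",
    "Hormonal and Palbocyclib",
    "Hormonal and Afinitor",
    "Hormonal",
    "Chemotherapy (carboplatin/gemzar)",
    "Chemotherapy (taxol)",
    "Targeted therapy for HER2",
)
_TREATMENT_WEIGHTS = (0.06, 0.06, 0.18, 0.08, 0.08, 0.22, 0.12, 0.20)


def simulate_metadata(n_patients: int, seed: int | None = None) -> list[PatientRecord]:
    """Simulate synthetic patient metadata mirroring the clinical table.

    One record per patient with ages at collection/diagnosis, an
    optional death age, IDC/ILC histology flags, HER2 status, a
    metastasis-site string ("Local disease", blank, or a comma-joined
    site list), and a free-text treatment.  Records round-trip through
    the metadata parser without loss.  Purely synthetic.
    """
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    rng = np.random.default_rng(seed)
    records: list[PatientRecord] = []
    for i in range(n_patients):
        age_coll = float(int(np.clip(rng.normal(53, 13), 25, 90)))
        age_diag = max(22.0, age_coll - float(rng.integers(0, 16)))
        age_death = age_coll + float(rng.integers(1, 3)) if rng.random() < 0.55 else None
        idc = bool(rng.random() < 0.93)
        status_draw = rng.random()
        if status_draw < 22 / 31:
            k = int(rng.integers(1, 4))
            sites = ", ".join(
                rng.choice(np.array(_METASTASIS_SITES), size=k, replace=False)
            )
        elif status_draw < 26 / 31:
            sites = "Local disease"
        else:
            sites = ""
        her2 = "+" if rng.random() < 9 / 31 else "-"
        treatment = str(rng.choice(np.array(_TREATMENTS), p=_TREATMENT_WEIGHTS))
        records.append(
            PatientRecord(
                patient_id=f"P{i + 1:02d}",
                age_collection=age_coll,
                age_diagnosis=age_diag,
                age_death=age_death,
                idc=idc,
                ilc=not idc,
                her2=her2,
                metastasis_sites=sites,
                treatment=treatment,
            )
        )
    return records
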