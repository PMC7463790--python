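"""End-to-end pipeline: quantify -> reproducibility -> compare -> permute -> summarize.

One YAML/JSON config drives the full analysis; all randomness flows from
a single master seed (per-stage streams are split off it in a fixed
order), every output is written under one directory, and a manifest
records the config, the seeds and a SHA-256 checksum of each output so
that a rerun with the same config is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import counts as counts_mod
from . import metadata as metadata_mod
from .cohort import compare_groups, per_target_summary, stratify_by_age
from .quantify import DEFAULT_NORMALIZER, PANEL_TARGETS, quantify_profiles, read_ct_csv
from .reproducibility import compare_within_between, cv_per_target, cv_reports_to_frame
from .subgroup import scan_treatment_labels

logger = logging.getLogger(__name__)

_STAGES = ("quantify", "reproducibility", "compare", "permute", "summarize", "counts")


class PipelineError(ValueError):
    """Configuration or stage failure; carries the stage name."""

    def __init__(self, stage: str, message: str) -> None:
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass(frozen=True)
class PipelineConfig:
    """Paths, panel definition, thresholds and seeds for one run."""

    ct_csv: str
    out_dir: str
    counts_tsv: str | None = None
    metadata_csv: str | None = None
    normalizer: str = DEFAULT_NORMALIZER
    targets: tuple[str, ...] = PANEL_TARGETS
    score_scale: str = "rel_expr"
    missing_policy: str = "strict"
    min_total_counts: int = 3
    presence_threshold: int = 49
    n_permutations: int = 1000
    age_cut: float | None = None  # None = pooled median
    treatment_labels: tuple[str, ...] = metadata_mod.DEFAULT_TREATMENT_LABELS
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as handle:
            raw = yaml.safe_load(handle) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise PipelineError("config", f"unknown config fields: {sorted(unknown)}")
        for key in ("targets", "treatment_labels"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def validate(self) -> None:
        if not self.ct_csv:
            raise PipelineError("config", "ct_csv is required")
        if not Path(self.ct_csv).exists():
            raise PipelineError("config", f"ct_csv does not exist: {self.ct_csv}")
        for name in ("counts_tsv", "metadata_csv"):
            value = getattr(self, name)
            if value is not None and not Path(value).exists():
                raise PipelineError("config", f"{name} does not exist: {value}")
        if self.n_permutations < 1:
            raise PipelineError("config", "n_permutations must be >= 1")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stage_seeds(master_seed: int) -> dict[str, int]:
    children = np.random.SeedSequence(master_seed).spawn(len(_STAGES))
    return {
        stage: int(child.generate_state(1)[0] % (2**31))
        for stage, child in zip(_STAGES, children)
    }


def run_pipeline(config: PipelineConfig) -> dict[str, str]:
    """Execute all applicable stages; return a name -> path map of outputs.

    A reproducibility stage runs only when the Ct table contains a
    repeat design (some subject sampled on >= 2 days); the permutation
    stage only when clinical metadata is configured; the count stage
    only when a count table is configured.  A stage failure aborts the
    run with the stage name while preserving the outputs already
    written.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    outputs: dict[str, str] = {}
    report_lines: list[str] = ["saliva splicing-factor panel — run report", ""]

    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w", encoding="utf-8")
    handler.setFormatter(logging.Formatter("%(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("sfpanel")
    root.addHandler(handler)
    root.setLevel(logging.INFO)

    def _write_frame(frame: pd.DataFrame, name: str) -> Path:
        path = out / name
        frame.to_csv(path, index=False)
        outputs[name] = str(path)
        return path

    try:
        # --- quantify ---------------------------------------------------
        try:
            ct = read_ct_csv(config.ct_csv)
            profiles = quantify_profiles(
                ct,
                normalizer=config.normalizer,
                targets=config.targets,
                score_scale=config.score_scale,
                missing_policy=config.missing_policy,
            )
            _write_frame(profiles, "profiles.csv")
            report_lines.append(f"quantified {len(profiles)} sample profiles")
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError("quantify", str(exc)) from exc

        # --- reproducibility (repeat design only) -----------------------
        try:
            days_per_subject = profiles.groupby("subject_id")["collection_day"].nunique()
            repeat_subjects = days_per_subject[days_per_subject >= 2]
            if len(repeat_subjects):
                repro_subject = repeat_subjects.idxmax()
                repro = profiles[profiles["subject_id"] == repro_subject]
                others = profiles[profiles["subject_id"] != repro_subject]
                diversity = others.sort_values("collection_day").drop_duplicates(
                    "subject_id"
                )
                reports = cv_per_target(repro, config.targets)
                _write_frame(cv_reports_to_frame(reports), "cv_report.csv")
                if len(diversity) >= 2:
                    comparison = compare_within_between(
                        repro,
                        diversity,
                        endpoints=list(config.targets) + ["composite"],
                        n_permutations=config.n_permutations,
                        seed=seeds["reproducibility"],
                    )
                    _write_frame(comparison, "variance_comparison.csv")
                report_lines.append(
                    f"reproducibility: subject {repro_subject} over "
                    f"{int(repeat_subjects.max())} days"
                )
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError("reproducibility", str(exc)) from exc

        # --- cohort comparison ------------------------------------------
        try:
            if profiles["group"].nunique() == 2:
                summary = per_target_summary(
                    profiles,
                    targets=config.targets,
                    n_permutations=config.n_permutations,
                    seed=seeds["compare"],
                )
                _write_frame(summary, "group_comparison.csv")
                composite_row = summary[summary["endpoint"] == "composite"].iloc[0]
                report_lines.append(
                    "composite comparison: p = "
                    f"{composite_row['p_raw']:.4g} ({composite_row['direction']})"
                )
                strata = stratify_by_age(profiles, config.age_cut)
                report_lines.append(
                    f"age strata at cut {strata.cut:g}: young n={len(strata.young)}, "
                    f"old n={len(strata.old)}"
                )
                if (
                    strata.young["group"].nunique() == 2
                    and strata.old["group"].nunique() == 2
                    and min(strata.young["group"].value_counts().min(),
                            strata.old["group"].value_counts().min()) >= 2
                ):
                    for name, stratum in (("young", strata.young), ("old", strata.old)):
                        res = compare_groups(
                            stratum,
                            n_permutations=config.n_permutations,
                            seed=seeds["compare"],
                        )
                        report_lines.append(
                            f"  {name} stratum composite p = {res.p_value:.4g}"
                        )
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError("compare", str(exc)) from exc

        # --- treatment permutation ---------------------------------------
        try:
            if config.metadata_csv is not None:
                records = metadata_mod.parse_metadata(config.metadata_csv)
                perm = scan_treatment_labels(
                    profiles,
                    records,
                    labels=config.treatment_labels,
                    n_permutations=config.n_permutations,
                    seed=seeds["permute"],
                )
                _write_frame(perm, "subgroup_permutations.csv")
                report_lines.append(
                    f"treatment permutation tests over {len(perm)} label(s)"
                )
                # --- cohort metadata summary -----------------------------
                summary = metadata_mod.summarize_cohort(
                    records, config.treatment_labels
                )
                path = out / "cohort_summary.json"
                path.write_text(
                    json.dumps(dataclasses.asdict(summary), indent=2, sort_keys=True)
                    + "\n",
                    encoding="utf-8",
                )
                outputs["cohort_summary.json"] = str(path)
                report_lines.append(
                    f"patient cohort: n={summary.n}, age "
                    f"{summary.age_mean:.1f} ± {summary.age_sd:.1f}, "
                    f"{summary.pct_metastatic:.1f}% metastatic"
                )
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError("permute", str(exc)) from exc

        # --- count filtering ----------------------------------------------
        try:
            if config.counts_tsv is not None:
                table = counts_mod.read_count_matrix(config.counts_tsv)
                filt_config = counts_mod.FilterConfig(
                    min_total_counts=config.min_total_counts,
                    presence_threshold=config.presence_threshold,
                )
                filtered, present, stage_log = counts_mod.apply_filters(
                    table, filt_config
                )
                path = out / "counts_filtered.tsv"
                counts_mod.write_count_matrix(filtered, path)
                outputs["counts_filtered.tsv"] = str(path)
                path = out / "present_genes.txt"
                path.write_text("\n".join(present) + "\n", encoding="utf-8")
                outputs["present_genes.txt"] = str(path)
                edges = [0, 1, 3, 10, 49, 100, 500, 1000, 10000]
                hist = counts_mod.abundance_histogram(filtered, edges)
                hist_frame = pd.DataFrame(
                    {
                        "bin_lo": edges[:-1],
                        "bin_hi": edges[1:],
                        "n_genes": hist,
                    }
                )
                _write_frame(hist_frame, "abundance_histogram.csv")
                report_lines.append(
                    "counts: "
                    + ", ".join(f"{k}={v}" for k, v in stage_log.items())
                )
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError("counts", str(exc)) from exc

        # --- report + manifest --------------------------------------------
        report_path = out / "report.txt"
        report_path.write_text("\n".join(report_lines) + "\n", encoding="utf-8")
        outputs["report.txt"] = str(report_path)

        manifest = {
            "config": {
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in dataclasses.asdict(config).items()
            },
            "master_seed": config.seed,
            "stage_seeds": seeds,
            "outputs": {
                name: _sha256(Path(path)) for name, path in sorted(outputs.items())
            },
        }
        manifest_path = out / "manifest.json"
        manifest_path.write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
        )
        outputs["manifest.json"] = str(manifest_path)
    finally:
        handler.close()
        root.removeHandler(handler)
    return outputs
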