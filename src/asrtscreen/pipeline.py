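"""End-to-end experiment orchestration.

``run_experiment`` composes the full analysis: synthetic cohort and recall
generation, text-pair featurization, tournament leave-pair-out evaluation of
the story-recall model (optionally with demographic and PACC5 comparison
models), DeLong/Youden ROC statistics, and pairwise model comparisons.
``run_screening`` produces the two screening-simulation tables.

Everything is deterministic given the configuration and seed; each report
carries a provenance block (config hash, seed, package version).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import (
    Participant,
    default_design,
    generate_cohort,
    generate_recalls,
    impute_education,
    pacc5_composite,
    scale_design,
)
from .rocstats import delong_ci, delong_test_paired, youden_metrics
from .screensim import (
    MMSE_MCI_META,
    PRESETS,
    ScreeningTest,
    compare_tests,
    derive_comparator,
    pet_enrichment,
    single_stratum,
)
from .stories import SYNTHETIC_STORIES
from .textpair import FEATURE_NAMES, story_vector
from .tlpo import ClassifierSpec, LabeledDataset, tlpo_auc

logger = logging.getLogger(__name__)

__all__ = [
    "ExperimentConfig",
    "ConfigError",
    "TASKS",
    "run_experiment",
    "run_screening",
    "featurize_records",
    "load_config",
]

#: task name -> (subsample filter, label function)
TASKS: dict[str, tuple[Any, Any]] = {
    "amyloid_full": (lambda p: True, lambda p: int(p.amyloid == "positive")),
    "mci_full": (lambda p: True, lambda p: int(p.is_impaired)),
    "amyloid_in_mci": (lambda p: p.is_impaired, lambda p: int(p.amyloid == "positive")),
    "amyloid_in_cu": (lambda p: not p.is_impaired, lambda p: int(p.amyloid == "positive")),
}


class ConfigError(ValueError):
    """Invalid experiment configuration; lists the offending keys."""


@dataclass(frozen=True)
class ExperimentConfig:
    seed: int = 0
    effect: str = "strong"
    n_per_group: int | None = None
    max_participants: int | None = None
    encoder: str = "surrogate"
    tlpo_mode: str = "all_pairs"
    tasks: tuple[str, ...] = tuple(TASKS)
    comparison_models: bool = False
    remove_fillers: bool = False
    outdir: str | None = None

    def validate(self) -> None:
        bad = []
        if not self.tasks:
            bad.append("tasks (empty)")
        for t in self.tasks:
            if t not in TASKS:
                bad.append(f"tasks ({t!r} unknown)")
        if self.tlpo_mode not in ("all_pairs", "cross_label_pairs"):
            bad.append("tlpo_mode")
        if self.encoder != "surrogate":
            bad.append("encoder")
        if self.effect not in ("strong", "moderate"):
            bad.append("effect")
        if self.n_per_group is not None and self.n_per_group < 2:
            bad.append("n_per_group")
        if bad:
            raise ConfigError(f"invalid configuration keys: {', '.join(sorted(bad))}")

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_config(path: str | Path) -> ExperimentConfig:
    """Read an :class:`ExperimentConfig` from a YAML file."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    known = {f.name for f in dataclasses.fields(ExperimentConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"invalid configuration keys: {', '.join(sorted(unknown))}")
    if "tasks" in raw:
        raw["tasks"] = tuple(raw["tasks"])
    return ExperimentConfig(**raw)


def featurize_records(records, remove_fillers: bool = False) -> pd.DataFrame:
    """Story-vector matrix: one row per (participant, story)."""
    rows = []
    for rec in records:
        sv = story_vector(rec, remove_fillers=remove_fillers)
        row = {"participant_id": sv.participant_id, "story_id": sv.story_id}
        row.update(dict(zip(sv.feature_names, sv.vector)))
        rows.append(row)
    return pd.DataFrame(rows)


def _subsample(cohort: list[Participant], max_n: int, seed: int) -> list[Participant]:
    """Deterministic per-group proportional subsample to at most ``max_n``."""
    if len(cohort) <= max_n:
        return cohort
    rng = np.random.default_rng(seed + 1)
    by_group: dict[int, list[Participant]] = {}
    for p in cohort:
        by_group.setdefault(p.group, []).append(p)
    frac = max_n / len(cohort)
    kept: list[Participant] = []
    for gid in sorted(by_group):
        members = by_group[gid]
        k = max(2, int(round(frac * len(members))))
        idx = rng.choice(len(members), size=min(k, len(members)), replace=False)
        kept.extend(members[i] for i in sorted(idx))
    return kept


def _roc_block(scores: np.ndarray, labels: np.ndarray) -> dict[str, Any]:
    roc = delong_ci(scores, labels)
    yj = youden_metrics(scores, labels)
    return {
        "auc": roc.auc,
        "se": roc.se,
        "ci_lower": roc.ci_lower,
        "ci_upper": roc.ci_upper,
        "z_vs_chance": roc.z,
        "p_vs_chance": roc.p_value,
        "degenerate": roc.degenerate,
        "youden": {
            "threshold": yj.threshold,
            "sensitivity": yj.sensitivity,
            "specificity": yj.specificity,
            "youden_j": yj.youden_j,
            "kappa": yj.kappa,
        },
    }


def _demographic_matrix(p: Participant) -> np.ndarray:
    # Sex enters the model as a binary indicator (female = 1).
    return np.array([[p.age, 1.0 if p.sex == "female" else 0.0, p.education]])


def run_experiment(config: ExperimentConfig) -> dict[str, Any]:
    """Execute the full pipeline and return the experiment report."""
    config.validate()
    design = default_design(config.effect)
    if config.n_per_group is not None:
        design = scale_design(design, config.n_per_group)
    logger.info("generating cohort (%d participants)", design.total_n())
    cohort = generate_cohort(design, config.seed)
    if config.max_participants is not None:
        cohort = _subsample(cohort, config.max_participants, config.seed)
    cohort = impute_education(cohort)
    records = generate_recalls(cohort, SYNTHETIC_STORIES, design, config.seed + 7)
    logger.info("featurizing %d records", len(records))
    story_df = featurize_records(records, remove_fillers=config.remove_fillers)

    by_id = {p.id: p for p in cohort}
    spec = ClassifierSpec()
    report: dict[str, Any] = {
        "provenance": {
            "config": dataclasses.asdict(config),
            "config_hash": config.config_hash(),
            "seed": config.seed,
            "version": __version__,
            "n_participants": len(cohort),
            "n_records": len(records),
        },
        "tasks": {},
    }

    for task in config.tasks:
        keep, labeler = TASKS[task]
        members = [p for p in cohort if keep(p)]
        labels = {p.id: labeler(p) for p in members}
        sub_df = story_df[story_df["participant_id"].isin(labels)]
        data = LabeledDataset.from_story_frame(sub_df, labels)
        logger.info("task %s: %d participants", task, len(members))
        result = tlpo_auc(data, spec=spec, mode=config.tlpo_mode)
        scores = np.asarray(result.scores)
        y = np.asarray(result.labels)
        block: dict[str, Any] = {
            "n": len(members),
            "n_folds": result.n_folds,
            "asrt": {"tlpo_auc": result.auc, **_roc_block(scores, y)},
        }

        if config.comparison_models:
            demo = LabeledDataset(
                participant_ids=[p.id for p in members],
                features={p.id: _demographic_matrix(p) for p in members},
                labels=labels,
            )
            demo_res = tlpo_auc(demo, spec=spec, mode=config.tlpo_mode)
            pacc_members = [
                p for p in members if pacc5_composite(p.pacc5_subtests) is not None
            ]
            pacc = LabeledDataset(
                participant_ids=[p.id for p in pacc_members],
                features={
                    p.id: np.array([[pacc5_composite(p.pacc5_subtests)]])
                    for p in pacc_members
                },
                labels={p.id: labels[p.id] for p in pacc_members},
            )
            pacc_res = tlpo_auc(pacc, spec=spec, mode=config.tlpo_mode)
            block["demographics"] = {
                "tlpo_auc": demo_res.auc,
                **_roc_block(np.asarray(demo_res.scores), np.asarray(demo_res.labels)),
            }
            block["pacc5"] = {
                "tlpo_auc": pacc_res.auc,
                "n": len(pacc_members),
                **_roc_block(np.asarray(pacc_res.scores), np.asarray(pacc_res.labels)),
            }
            z, p_val = delong_test_paired(scores, np.asarray(demo_res.scores), y)
            block["asrt_vs_demographics"] = {"z": z, "p": p_val}
            pacc_ids = set(pacc.participant_ids)
            mask = np.array([pid in pacc_ids for pid in result.participant_ids])
            z2, p2 = delong_test_paired(
                scores[mask], np.asarray(pacc_res.scores), y[mask]
            )
            block["asrt_vs_pacc5"] = {"z": z2, "p": p2}

        report["tasks"][task] = block

    if config.outdir:
        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "report.json").write_text(json.dumps(report, indent=2))
        story_df.to_csv(outdir / "story_vectors.csv", index=False)
        (outdir / "feature_schema.json").write_text(
            json.dumps({"features": list(FEATURE_NAMES)}, indent=2)
        )
    return report


def run_screening(
    asrt_test: ScreeningTest | None = None,
    n_population: int = 1000,
) -> dict[str, Any]:
    """The two shipped screening scenarios.

    *MCI primary-care screening*: MMSE meta-analytic operating point versus a
    story-recall comparator, at the age-65+ aggregate MCI prevalence, in a
    hypothetical sample of ``n_population``.  When ``asrt_test`` is not
    given, the comparator is derived from the reported relative deltas
    (+8.5% detection, -59.1% false positives) applied to the MMSE point.

    *PET pre-screening enrichment*: scans and recruitment needed to reach a
    fixed number of confirmed amyloid-positive participants in MCI and CU
    populations, pre-screening with the same comparator.
    """
    comparator = asrt_test or derive_comparator(
        MMSE_MCI_META, detection_change=0.085, false_positive_change=-0.591, name="ASRT"
    )
    pop = single_stratum(PRESETS["mci_65plus"], n_population, age_band="65+")
    comparison = compare_tests(comparator, MMSE_MCI_META, pop)

    out: dict[str, Any] = {
        "mci_screening": {
            "prevalence": pop.prevalence,
            "n": n_population,
            "mmse": {
                "sensitivity": MMSE_MCI_META.sensitivity,
                "specificity": MMSE_MCI_META.specificity,
                "ppv": comparison.outcome_b.ppv,
                "npv": comparison.outcome_b.npv,
                "detected": comparison.outcome_b.detected,
                "false_positives": comparison.outcome_b.false_positives,
            },
            "asrt": {
                "sensitivity": comparator.sensitivity,
                "specificity": comparator.specificity,
                "ppv": comparison.outcome_a.ppv,
                "npv": comparison.outcome_a.npv,
                "detected": comparison.outcome_a.detected,
                "false_positives": comparison.outcome_a.false_positives,
            },
            "detection_change": comparison.detection_change,
            "false_positive_change": comparison.false_positive_change,
        },
        "pet_enrichment": {},
    }
    for label, preset in (("mci", "abeta_positive_mci"), ("cu", "abeta_positive_cu")):
        enr = pet_enrichment(PRESETS[preset], comparator, target_positive=100)
        out["pet_enrichment"][label] = {
            "prevalence": PRESETS[preset],
            "target_positive": enr.target_positive,
            "scans_without_prescreen": enr.scans_without_prescreen,
            "scans_with_prescreen": enr.scans_with_prescreen,
            "recruited_with_prescreen": enr.recruited_with_prescreen,
            "scan_reduction": enr.scan_reduction,
            "recruitment_increase": enr.recruitment_increase,
            "prescreen_ppv": enr.prescreen_ppv,
        }
    return out


def screening_tables(results: dict[str, Any]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Human-readable TSV-able tables from :func:`run_screening` output."""
    mci = results["mci_screening"]
    rows = []
    for name in ("mmse", "asrt"):
        t = mci[name]
        rows.append(
            {
                "test": name.upper(),
                "sensitivity": t["sensitivity"],
                "specificity": t["specificity"],
                "ppv_pct": 100 * t["ppv"],
                "npv_pct": 100 * t["npv"],
                "detected": t["detected"],
                "false_positives": t["false_positives"],
            }
        )
    screen_tbl = pd.DataFrame(rows)
    enr_rows = []
    for label, e in results["pet_enrichment"].items():
        enr_rows.append(
            {
                "population": label.upper(),
                "prevalence": e["prevalence"],
                "scan_reduction_pct": 100 * e["scan_reduction"],
                "recruitment_increase_pct": 100 * e["recruitment_increase"],
                "scans_without": e["scans_without_prescreen"],
                "scans_with": e["scans_with_prescreen"],
            }
        )
    return screen_tbl, pd.DataFrame(enr_rows)
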