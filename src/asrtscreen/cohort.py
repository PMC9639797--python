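"""Synthetic cohort and story-recall generation for a 2x2 amyloid x diagnosis design.

The study design crosses clinical status (MCI/mild AD vs cognitively
unimpaired, CU) with amyloid-beta biomarker status (positive vs negative)
into four groups:

* Group 1 — amyloid-positive MCI/mild AD
* Group 2 — amyloid-negative MCI/mild AD
* Group 3 — amyloid-positive CU
* Group 4 — amyloid-negative CU

``generate_cohort`` draws demographics, MMSE, CDR-G and PACC5 subtest
z-scores per group; ``generate_recalls`` produces synthetic story-recall
transcripts by degrading the source text with group-dependent token
omission, substitution and filler insertion (delayed recall adds further
omission).  The degradation model is an invented stand-in for recorded
recalls — its rates are configuration, not estimates.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .textpair import DEFAULT_FILLER_LEXICON, normalize_transcript

__all__ = [
    "Participant",
    "GroupSpec",
    "GroupDesign",
    "ASRTRecord",
    "PACC5_SUBTESTS",
    "GROUP_LABELS",
    "default_design",
    "generate_cohort",
    "generate_recalls",
    "pacc5_composite",
    "impute_education",
    "cohort_to_dataframe",
    "dataframe_to_cohort",
    "write_cohort_csv",
    "read_cohort_csv",
    "write_records_jsonl",
    "read_records_jsonl",
    "read_records_directory",
]

PACC5_SUBTESTS: tuple[str, ...] = (
    "mmse_z",
    "logical_memory_z",
    "digit_symbol_z",
    "fcsrt_z",
    "category_fluency_z",
)

#: group id -> (diagnosis class, amyloid status); "MCI" here means MCI/mild AD.
GROUP_LABELS: dict[int, tuple[str, str]] = {
    1: ("MCI", "positive"),
    2: ("MCI", "negative"),
    3: ("CU", "positive"),
    4: ("CU", "negative"),
}

# MMSE eligibility windows by clinical class.
_MMSE_WINDOW = {"MCI": (23, 30), "mild_AD": (23, 30), "CU": (26, 30)}
_AGE_WINDOW = (50.0, 85.0)


@dataclass(frozen=True)
class Participant:
    id: str
    site: str  # "UK" | "US"
    age: float
    sex: str  # "female" | "male"
    education: float | None
    diagnosis: str  # "CU" | "MCI" | "mild_AD"
    amyloid: str  # "positive" | "negative"
    mmse: int
    cdr_g: float
    pacc5_subtests: dict[str, float | None] = field(default_factory=dict)

    @property
    def group(self) -> int:
        clinical = "CU" if self.diagnosis == "CU" else "MCI"
        for gid, (diag, amy) in GROUP_LABELS.items():
            if diag == clinical and amy == self.amyloid:
                return gid
        raise ValueError(f"unclassifiable participant {self.id}")

    @property
    def is_impaired(self) -> bool:
        return self.diagnosis != "CU"


@dataclass(frozen=True)
class ASRTRecord:
    participant_id: str
    story_id: int
    source_text: str
    immediate_recall: str
    delayed_recall: str
    transcript_kind: str = "synthetic"


@dataclass(frozen=True)
class GroupSpec:
    """Per-group sampling parameters: demographics plus recall degradation."""

    n: int
    age_mean: float
    age_sd: float
    female_fraction: float
    education_mean: float
    education_sd: float
    mmse_mean: float
    mmse_sd: float
    cdr_values: tuple[float, ...]
    cdr_probs: tuple[float, ...]
    pacc5_mean: float
    pacc5_sd: float
    mild_ad_fraction: float
    omission_rate: float
    substitution_rate: float
    filler_insertion_rate: float
    delayed_extra_omission_rate: float

    def validate(self, group_id: int) -> None:
        if self.n <= 0:
            raise ValueError(f"group {group_id}: sample size must be positive")
        for attr in (
            "omission_rate",
            "substitution_rate",
            "filler_insertion_rate",
            "delayed_extra_omission_rate",
            "female_fraction",
            "mild_ad_fraction",
        ):
            v = getattr(self, attr)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"group {group_id}: {attr} must lie in [0, 1]")
        if abs(sum(self.cdr_probs) - 1.0) > 1e-9:
            raise ValueError(f"group {group_id}: cdr_probs must sum to 1")


@dataclass(frozen=True)
class GroupDesign:
    """The full 2x2 design: one GroupSpec per group plus missingness rates."""

    groups: dict[int, GroupSpec]
    education_missing_rate: float = 0.015
    pacc5_missing_rate: float = 0.115
    uk_fraction: float = 0.5

    def validate(self) -> None:
        if set(self.groups) != {1, 2, 3, 4}:
            raise ValueError("design must define groups 1-4")
        for gid, spec in self.groups.items():
            spec.validate(gid)
        # Impaired groups must degrade at least as much as unimpaired ones
        # at the same amyloid status (group 1 >= 3, group 2 >= 4).
        for rate in ("omission_rate", "substitution_rate", "filler_insertion_rate"):
            for mci_gid, cu_gid in ((1, 3), (2, 4)):
                if getattr(self.groups[mci_gid], rate) < getattr(
                    self.groups[cu_gid], rate
                ) - 1e-12:
                    raise ValueError(
                        f"{rate}: MCI/mild-AD group {mci_gid} must be >= CU group {cu_gid}"
                    )

    def total_n(self) -> int:
        return sum(s.n for s in self.groups.values())


def default_design(effect: str = "strong") -> GroupDesign:
    """The default study conditions.

    Demographics follow the recruited sample's per-group means/SDs; the
    recall-degradation rates define the synthetic effect size.  ``strong``
    is the separable regime used for end-to-end recovery checks; ``moderate``
    reduces the between-group contrast.
    """
    if effect not in ("strong", "moderate"):
        raise ValueError("effect must be 'strong' or 'moderate'")
    # (omission, substitution, filler insertion, delayed extra omission).
    # Two factorial main effects: clinical status drives omission and filler
    # insertion (impoverished, hesitant recall), amyloid status drives
    # substitution and the extra delayed-recall omission (error-prone recall
    # and faster decay).  Keeping the two effects on distinct token
    # operations makes all four classification tasks identifiable.
    degradation = {
        "strong": {
            1: (0.35, 0.20, 0.15, 0.15),
            2: (0.35, 0.04, 0.15, 0.04),
            3: (0.10, 0.20, 0.05, 0.15),
            4: (0.10, 0.04, 0.05, 0.04),
        },
        "moderate": {
            1: (0.28, 0.10, 0.10, 0.08),
            2: (0.28, 0.05, 0.10, 0.04),
            3: (0.18, 0.10, 0.06, 0.08),
            4: (0.18, 0.05, 0.06, 0.04),
        },
    }[effect]
    demographics = {
        # group: (n, age_mean, age_sd, female_frac, edu_mean, edu_sd,
        #         mmse_mean, mmse_sd, pacc5_mean)
        1: (46, 72.72, 5.95, 21 / 46, 15.22, 3.09, 26.64, 2.18, -1.2),
        2: (54, 68.65, 7.45, 34 / 54, 14.92, 2.81, 26.89, 2.16, -1.0),
        3: (47, 71.43, 4.77, 27 / 47, 15.06, 3.53, 28.77, 1.43, -0.2),
        4: (46, 69.41, 4.10, 28 / 46, 15.75, 3.08, 28.78, 1.07, 0.0),
    }
    cdr = {
        1: ((0.5, 1.0), (0.86, 0.14)),
        2: ((0.5, 1.0), (0.92, 0.08)),
        3: ((0.0, 0.5), (0.76, 0.24)),
        4: ((0.0, 0.5), (0.82, 0.18)),
    }
    groups = {}
    for gid, (n, am, asd, ff, em, esd, mm, msd, pm) in demographics.items():
        om, sub, fil, extra = degradation[gid]
        groups[gid] = GroupSpec(
            n=n,
            age_mean=am,
            age_sd=asd,
            female_fraction=ff,
            education_mean=em,
            education_sd=esd,
            mmse_mean=mm,
            mmse_sd=msd,
            cdr_values=cdr[gid][0],
            cdr_probs=cdr[gid][1],
            pacc5_mean=pm,
            pacc5_sd=0.8,
            mild_ad_fraction=0.123 if gid in (1, 2) else 0.0,
            omission_rate=om,
            substitution_rate=sub,
            filler_insertion_rate=fil,
            delayed_extra_omission_rate=extra,
        )
    return GroupDesign(groups=groups)


def scale_design(design: GroupDesign, n_per_group: int) -> GroupDesign:
    """Same design with every group's sample size set to ``n_per_group``."""
    groups = {
        gid: dataclasses.replace(spec, n=n_per_group)
        for gid, spec in design.groups.items()
    }
    return dataclasses.replace(design, groups=groups)


def generate_cohort(design: GroupDesign, seed: int) -> list[Participant]:
    """Draw a cohort matching the design's group sizes exactly.

    Ages are normal per group, truncated to the eligibility window [50, 85];
    MMSE is normal, rounded and clipped to the diagnosis-specific window
    (23-30 for MCI/mild AD, 26-30 for CU).  Education and PACC5 subtests
    carry missing-completely-at-random gaps at the design's rates.
    """
    design.validate()
    rng = np.random.default_rng(seed)
    cohort: list[Participant] = []
    counter = 0
    for gid in sorted(design.groups):
        spec = design.groups[gid]
        clinical, amyloid = GROUP_LABELS[gid]
        for _ in range(spec.n):
            counter += 1
            pid = f"P{counter:04d}"
            age = float(rng.normal(spec.age_mean, spec.age_sd))
            age = float(np.clip(age, *_AGE_WINDOW))
            sex = "female" if rng.random() < spec.female_fraction else "male"
            site = "UK" if rng.random() < design.uk_fraction else "US"
            education: float | None = float(
                np.clip(rng.normal(spec.education_mean, spec.education_sd), 6, 24)
            )
            if rng.random() < design.education_missing_rate:
                education = None
            diagnosis = clinical
            if clinical == "MCI" and rng.random() < spec.mild_ad_fraction:
                diagnosis = "mild_AD"
            lo, hi = _MMSE_WINDOW[diagnosis]
            mmse = int(np.clip(round(rng.normal(spec.mmse_mean, spec.mmse_sd)), lo, hi))
            cdr = float(rng.choice(spec.cdr_values, p=spec.cdr_probs))
            subtests: dict[str, float | None] = {
                name: float(rng.normal(spec.pacc5_mean, spec.pacc5_sd))
                for name in PACC5_SUBTESTS
            }
            if rng.random() < design.pacc5_missing_rate:
                n_drop = int(rng.integers(1, len(PACC5_SUBTESTS)))
                for name in rng.choice(PACC5_SUBTESTS, size=n_drop, replace=False):
                    subtests[str(name)] = None
            cohort.append(
                Participant(
                    id=pid,
                    site=site,
                    age=age,
                    sex=sex,
                    education=education,
                    diagnosis=diagnosis,
                    amyloid=amyloid,
                    mmse=mmse,
                    cdr_g=cdr,
                    pacc5_subtests=subtests,
                )
            )
    return cohort


def _degrade(
    tokens: Sequence[str],
    vocab: Sequence[str],
    omission: float,
    substitution: float,
    filler: float,
    rng: np.random.Generator,
) -> list[str]:
    fillers = sorted(DEFAULT_FILLER_LEXICON)
    out: list[str] = []
    for tok in tokens:
        if rng.random() < omission:
            continue
        if rng.random() < substitution:
            tok = str(vocab[rng.integers(0, len(vocab))])
        out.append(tok)
        if rng.random() < filler:
            out.append(fillers[rng.integers(0, len(fillers))])
    return out


def generate_recalls(
    cohort: Sequence[Participant],
    source_stories: Sequence[str],
    design: GroupDesign,
    seed: int,
) -> list[ASRTRecord]:
    """One synthetic record per participant x story.

    Immediate recall degrades the source tokens at the participant's group
    rates; delayed recall adds the group's extra omission on top.
    """
    if not source_stories:
        raise ValueError("at least one source story is required")
    if any(not s.strip() for s in source_stories):
        raise ValueError("source stories must be non-empty")
    if not cohort:
        raise ValueError("cohort must be non-empty")
    design.validate()
    story_tokens = [normalize_transcript(s).tokens for s in source_stories]
    vocab = sorted({t for toks in story_tokens for t in toks})
    rng = np.random.default_rng(seed)
    records: list[ASRTRecord] = []
    for participant in cohort:
        spec = design.groups[participant.group]
        for sid, (story, tokens) in enumerate(zip(source_stories, story_tokens), start=1):
            immediate = _degrade(
                tokens,
                vocab,
                spec.omission_rate,
                spec.substitution_rate,
                spec.filler_insertion_rate,
                rng,
            )
            delayed = _degrade(
                tokens,
                vocab,
                min(1.0, spec.omission_rate + spec.delayed_extra_omission_rate),
                spec.substitution_rate,
                spec.filler_insertion_rate,
                rng,
            )
            records.append(
                ASRTRecord(
                    participant_id=participant.id,
                    story_id=sid,
                    source_text=story,
                    immediate_recall=" ".join(immediate),
                    delayed_recall=" ".join(delayed),
                    transcript_kind="synthetic",
                )
            )
    return records


def pacc5_composite(subtests: dict[str, float | None]) -> float | None:
    """Mean z-score over the available PACC5 subtests.

    Missing subtests are simply excluded; with no subtests available the
    composite itself is missing (``None``), never zero.
    """
    values = [v for v in subtests.values() if v is not None]
    if not values:
        return None
    return float(np.mean(values))


def impute_education(cohort: Sequence[Participant]) -> list[Participant]:
    """Replace missing years-of-education with the sample median.

    The median is taken over the non-missing values of the analysis sample;
    an even count uses the mean of the two central values.
    """
    observed = sorted(p.education for p in cohort if p.education is not None)
    if not observed:
        raise ValueError("cannot impute education: all values missing")
    median = float(np.median(observed))
    return [
        dataclasses.replace(p, education=median) if p.education is None else p
        for p in cohort
    ]


# ---------------------------------------------------------------------------
# I/O

def cohort_to_dataframe(cohort: Sequence[Participant]) -> pd.DataFrame:
    rows = []
    for p in cohort:
        row = {
            "id": p.id,
            "site": p.site,
            "age": p.age,
            "sex": p.sex,
            "education": p.education,
            "diagnosis": p.diagnosis,
            "amyloid": p.amyloid,
            "mmse": p.mmse,
            "cdr_g": p.cdr_g,
        }
        for name in PACC5_SUBTESTS:
            row[name] = p.pacc5_subtests.get(name)
        rows.append(row)
    return pd.DataFrame(rows)


def dataframe_to_cohort(df: pd.DataFrame) -> list[Participant]:
    cohort = []
    for _, row in df.iterrows():
        subtests = {
            name: (None if pd.isna(row[name]) else float(row[name]))
            for name in PACC5_SUBTESTS
        }
        cohort.append(
            Participant(
                id=str(row["id"]),
                site=str(row["site"]),
                age=float(row["age"]),
                sex=str(row["sex"]),
                education=None if pd.isna(row["education"]) else float(row["education"]),
                diagnosis=str(row["diagnosis"]),
                amyloid=str(row["amyloid"]),
                mmse=int(row["mmse"]),
                cdr_g=float(row["cdr_g"]),
                pacc5_subtests=subtests,
            )
        )
    return cohort


def write_cohort_csv(cohort: Sequence[Participant], path: str | Path) -> None:
    cohort_to_dataframe(cohort).to_csv(path, index=False)


def read_cohort_csv(path: str | Path) -> list[Participant]:
    return dataframe_to_cohort(pd.read_csv(path))


def write_records_jsonl(records: Iterable[ASRTRecord], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            fh.write(json.dumps(dataclasses.asdict(rec), ensure_ascii=False) + "\n")


def read_records_jsonl(path: str | Path) -> list[ASRTRecord]:
    records = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line:
                records.append(ASRTRecord(**json.loads(line)))
    return records


def read_records_directory(root: str | Path) -> list[ASRTRecord]:
    """Read records from ``<root>/<participant_id>/story<k>_{source,immediate,delayed}.txt``."""
    root = Path(root)
    records = []
    for pdir in sorted(d for d in root.iterdir() if d.is_dir()):
        story_ids = sorted(
            int(f.stem.split("_")[0].removeprefix("story"))
            for f in pdir.glob("story*_source.txt")
        )
        for sid in story_ids:
            texts = {}
            for slot in ("source", "immediate", "delayed"):
                fpath = pdir / f"story{sid}_{slot}.txt"
                texts[slot] = fpath.read_text(encoding="utf-8") if fpath.exists() else ""
            records.append(
                ASRTRecord(
                    participant_id=pdir.name,
                    story_id=sid,
                    source_text=texts["source"],
                    immediate_recall=texts["immediate"],
                    delayed_recall=texts["delayed"],
                    transcript_kind="manual",
                )
            )
    return records
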