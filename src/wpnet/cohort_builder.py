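"""Cohort construction from raw claims: ICD matching, filtering, profiles.

This module turns long-format admission claims into per-patient profiles
ready for network construction:

* ICD code patterns (literals, wildcard prefixes such as ``428.x``,
  inclusive ranges such as ``J40.x–J47.x``) and comorbidity grouping tables
  loaded from YAML;
* the three admission filters — at least two episodes, only episodes
  carrying codes relevant to the grouping table, at most 50 episodes;
* patient features (min–max-normalised age, gender, smoking flag derived
  from the smoking code group) and case labels from the target disease
  definition;
* balanced control sampling.

Range semantics: endpoints share an alphabetic prefix; the numeric remainder
is compared as (integer category, decimal fraction), and an endpoint carrying
a ``.x`` wildcard spans its whole category.  A range whose endpoints have
different alphabetic prefixes (or are reversed) is syntactically valid but
matches nothing — this keeps verbatim published tables loadable even when
they contain misprinted ranges.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import (
    ConfigurationError,
    DataIntegrityError,
    EmptyCohortError,
    PatternSyntaxError,
)

__all__ = [
    "CodePattern",
    "DiseaseDefinition",
    "GroupingTable",
    "PatientProfile",
    "match_code",
    "filter_patients",
    "build_profiles",
    "normalize_age",
    "sample_balanced_controls",
    "SMOKING_GROUP",
]

SMOKING_GROUP = "smoking"

_DASHES = "–—"  # en dash, em dash
_CODE_RE = re.compile(r"^([A-Z]*)(\d+)(?:\.(\d+))?$")


def _normalize(raw: str) -> str:
    s = raw.strip().upper().replace(".*", ".X")
    for d in _DASHES:
        s = s.replace(d, "-")
    return s


def _code_key(code: str) -> tuple[str, int, float] | None:
    """Decompose a code into (alpha prefix, integer category, decimal fraction)."""
    m = _CODE_RE.match(code)
    if m is None:
        return None
    alpha, major, frac = m.groups()
    frac_val = float(f"0.{frac}") if frac else 0.0
    return alpha, int(major), frac_val


@dataclass(frozen=True)
class CodePattern:
    """One parsed ICD code pattern: literal, wildcard prefix, or range."""

    raw: str
    icd_version: int
    kind: str = field(init=False)
    _literal: str = field(init=False, default="")
    _prefix: str = field(init=False, default="")
    _lo: tuple = field(init=False, default=())
    _hi: tuple = field(init=False, default=())

    def __post_init__(self) -> None:
        s = _normalize(self.raw)
        if not s:
            raise PatternSyntaxError(self.raw, "empty pattern")
        if "-" in s:
            parts = s.split("-")
            if len(parts) != 2 or not parts[0] or not parts[1]:
                raise PatternSyntaxError(self.raw, "range needs two endpoints")
            lo = self._endpoint(parts[0], low=True)
            hi = self._endpoint(parts[1], low=False)
            object.__setattr__(self, "kind", "range")
            object.__setattr__(self, "_lo", lo)
            object.__setattr__(self, "_hi", hi)
        elif s.endswith(".X") or (s.endswith("X") and len(s) > 1 and s[-2].isdigit()):
            prefix = s[:-2] if s.endswith(".X") else s[:-1]
            if _code_key(prefix) is None:
                raise PatternSyntaxError(self.raw, f"bad wildcard prefix {prefix!r}")
            object.__setattr__(self, "kind", "wildcard")
            object.__setattr__(self, "_prefix", prefix)
        else:
            if _code_key(s) is None:
                raise PatternSyntaxError(self.raw, "not a literal code, wildcard or range")
            object.__setattr__(self, "kind", "literal")
            object.__setattr__(self, "_literal", s)

    def _endpoint(self, s: str, *, low: bool) -> tuple[str, int, float]:
        wildcard = s.endswith(".X") or (s.endswith("X") and len(s) > 1 and s[-2].isdigit())
        if wildcard:
            s = s[:-2] if s.endswith(".X") else s[:-1]
        key = _code_key(s)
        if key is None:
            raise PatternSyntaxError(self.raw, f"bad range endpoint {s!r}")
        alpha, major, frac = key
        if wildcard:
            # A ".x" endpoint spans its whole category.
            frac = -np.inf if low else np.inf
        return alpha, major, frac

    def matches(self, code: str) -> bool:
        c = _normalize(code)
        if self.kind == "literal":
            return c == self._literal
        if self.kind == "wildcard":
            return c == self._prefix or c.startswith(self._prefix + ".")
        key = _code_key(c)
        if key is None:
            return False
        alpha, major, frac = key
        lo_a, lo_m, lo_f = self._lo
        hi_a, hi_m, hi_f = self._hi
        if alpha != lo_a or alpha != hi_a:
            return False
        return (lo_m, lo_f) <= (major, frac) <= (hi_m, hi_f)


def match_code(code: str, pattern: CodePattern) -> bool:
    """True iff ``code`` matches the parsed pattern (pure function)."""
    return pattern.matches(code)


@dataclass(frozen=True)
class DiseaseDefinition:
    """Named disease/comorbidity group with per-ICD-version pattern lists."""

    name: str
    patterns_icd9: tuple[CodePattern, ...] = ()
    patterns_icd10: tuple[CodePattern, ...] = ()

    def __post_init__(self) -> None:
        if not self.patterns_icd9 and not self.patterns_icd10:
            raise ConfigurationError(
                f"disease {self.name!r} has no patterns for any ICD version"
            )

    def matches(self, code: str, icd_version: int) -> bool:
        patterns = self.patterns_icd9 if icd_version == 9 else self.patterns_icd10
        return any(p.matches(code) for p in patterns)

    @classmethod
    def from_lists(
        cls, name: str, icd9: list[str] | None, icd10: list[str] | None
    ) -> "DiseaseDefinition":
        return cls(
            name=name,
            patterns_icd9=tuple(CodePattern(raw, 9) for raw in (icd9 or [])),
            patterns_icd10=tuple(CodePattern(raw, 10) for raw in (icd10 or [])),
        )


class GroupingTable:
    """Mapping from comorbidity-group name to :class:`DiseaseDefinition`."""

    def __init__(self, definitions: dict[str, DiseaseDefinition]):
        if len(definitions) == 0:
            raise ConfigurationError("grouping table is empty")
        self.definitions = dict(definitions)

    def __contains__(self, name: str) -> bool:
        return name in self.definitions

    def __getitem__(self, name: str) -> DiseaseDefinition:
        return self.definitions[name]

    @property
    def names(self) -> list[str]:
        return list(self.definitions)

    def matching_groups(self, code: str, icd_version: int) -> set[str]:
        """All group names whose definition matches (code, version)."""
        return {
            name
            for name, d in self.definitions.items()
            if d.matches(code, icd_version)
        }

    def matches_any(self, code: str, icd_version: int) -> bool:
        return any(d.matches(code, icd_version) for d in self.definitions.values())

    @classmethod
    def from_yaml(cls, path: str | Path) -> "GroupingTable":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls._from_doc(doc, source=str(path))

    @classmethod
    def default(cls, variant: str = "corrected") -> "GroupingTable":
        """Load the packaged grouping table (``corrected`` or ``printed``)."""
        fname = {
            "corrected": "comorbidity_groups.yaml",
            "printed": "comorbidity_groups_printed.yaml",
        }.get(variant)
        if fname is None:
            raise ConfigurationError(f"unknown grouping variant {variant!r}")
        ref = resources.files("wpnet.data").joinpath(fname)
        doc = yaml.safe_load(ref.read_text())
        return cls._from_doc(doc, source=fname)

    @classmethod
    def _from_doc(cls, doc: dict, source: str) -> "GroupingTable":
        if not isinstance(doc, dict) or "groups" not in doc:
            raise ConfigurationError(f"{source}: expected a top-level 'groups' mapping")
        defs: dict[str, DiseaseDefinition] = {}
        for name, lists in doc["groups"].items():
            if name in defs:
                raise ConfigurationError(f"{source}: duplicate group {name!r}")
            defs[name] = DiseaseDefinition.from_lists(
                name, lists.get("icd9"), lists.get("icd10")
            )
        return cls(defs)


@dataclass
class PatientProfile:
    """Per-patient features, label, and grouped diagnosis set."""

    patient_id: str
    age: float
    age_norm: float
    gender: int
    smoking: int
    grouped_diagnoses: frozenset[str]
    label: int


def _episode_counts(claims: pd.DataFrame) -> pd.Series:
    return claims.groupby("patient_id")["episode_id"].nunique()


def filter_patients(
    claims: pd.DataFrame, grouping: GroupingTable
) -> pd.DataFrame:
    """Apply the three admission filters to a claims table.

    (i) drop patients with fewer than 2 distinct episodes, (iii) drop
    patients with more than 50 distinct episodes, (ii) drop episode rows
    whose code matches no group in the grouping table, then re-apply the
    minimum-episode criterion to the surviving rows.  Raises
    :class:`EmptyCohortError` rather than returning an empty table.
    """
    if claims.empty:
        raise EmptyCohortError("input claims table is empty")
    counts = _episode_counts(claims)
    keep = counts[(counts >= 2) & (counts <= 50)].index
    out = claims[claims["patient_id"].isin(keep)]

    if not out.empty:
        pairs = out[["icd_code", "icd_version"]].drop_duplicates()
        relevant = {
            (c, v)
            for c, v in pairs.itertuples(index=False)
            if grouping.matches_any(str(c), int(v))
        }
        mask = [
            (str(c), int(v)) in relevant
            for c, v in zip(out["icd_code"], out["icd_version"])
        ]
        out = out[mask]

    if not out.empty:
        counts = _episode_counts(out)
        keep = counts[counts >= 2].index
        out = out[out["patient_id"].isin(keep)]

    if out.empty:
        raise EmptyCohortError("no patients survive the admission filters")
    return out.reset_index(drop=True)


def normalize_age(ages) -> np.ndarray:
    """Min–max scale ages to [0, 1] over the cohort; constant cohorts map to 0."""
    arr = np.asarray(ages, dtype=float)
    if arr.size == 0:
        raise ConfigurationError("normalize_age requires a nonempty list")
    if np.any(arr <= 0):
        raise ConfigurationError("ages must be positive")
    span = arr.max() - arr.min()
    if span == 0:
        return np.zeros_like(arr)
    return (arr - arr.min()) / span


def build_profiles(
    claims: pd.DataFrame,
    target: DiseaseDefinition,
    grouping: GroupingTable,
) -> list[PatientProfile]:
    """Build one :class:`PatientProfile` per patient from filtered claims.

    The label is 1 iff any of the patient's codes matches the target disease
    definition; smoking is 1 iff any code matches the smoking group; the
    grouped diagnosis set collects every matching comorbidity-group name
    (including the target's) except the smoking group, which is a behavioural
    feature rather than a disease node.
    """
    if claims.empty:
        raise EmptyCohortError("cannot build profiles from an empty table")

    demo = claims.groupby("patient_id")[["age", "gender"]].nunique()
    bad = demo[(demo["age"] > 1) | (demo["gender"] > 1)].index.tolist()
    if bad:
        raise DataIntegrityError(
            f"inconsistent age/gender across rows for patient(s): {bad}"
        )

    # Match each distinct (code, version) once, then fan out to patients.
    pairs = claims[["icd_code", "icd_version"]].drop_duplicates()
    group_cache: dict[tuple[str, int], set[str]] = {}
    target_cache: dict[tuple[str, int], bool] = {}
    for c, v in pairs.itertuples(index=False):
        key = (str(c), int(v))
        group_cache[key] = grouping.matching_groups(*key)
        target_cache[key] = target.matches(*key)

    profiles: list[PatientProfile] = []
    order = sorted(claims["patient_id"].unique())
    ages = claims.groupby("patient_id")["age"].first()
    genders = claims.groupby("patient_id")["gender"].first()
    age_norm = normalize_age(ages.loc[order].to_numpy())
    by_patient = claims.groupby("patient_id")

    for i, pid in enumerate(order):
        rows = by_patient.get_group(pid)
        groups: set[str] = set()
        label = 0
        for c, v in zip(rows["icd_code"], rows["icd_version"]):
            key = (str(c), int(v))
            groups |= group_cache[key]
            if target_cache[key]:
                label = 1
        smoking = 1 if SMOKING_GROUP in groups else 0
        groups.discard(SMOKING_GROUP)
        profiles.append(
            PatientProfile(
                patient_id=pid,
                age=float(ages.loc[pid]),
                age_norm=float(age_norm[i]),
                gender=int(genders.loc[pid]),
                smoking=smoking,
                grouped_diagnoses=frozenset(groups),
                label=label,
            )
        )
    return profiles


def sample_balanced_controls(
    cases: list[PatientProfile],
    eligible_controls: list[PatientProfile],
    seed: int = 0,
) -> list[PatientProfile]:
    """Sample |cases| controls uniformly without replacement (reproducible)."""
    n = len(cases)
    if len(eligible_controls) < n:
        raise ConfigurationError(
            f"need at least {n} eligible controls, have {len(eligible_controls)}"
        )
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(eligible_controls), size=n, replace=False)
    return [eligible_controls[i] for i in sorted(idx)]


def profiles_to_frame(profiles: list[PatientProfile]) -> pd.DataFrame:
    """Wide per-patient feature table (patient_id, age_norm, gender, smoking, label)."""
    return pd.DataFrame(
        {
            "patient_id": [p.patient_id for p in profiles],
            "age_norm": [p.age_norm for p in profiles],
            "gender": [p.gender for p in profiles],
            "smoking": [p.smoking for p in profiles],
            "label": [p.label for p in profiles],
        }
    )


def profiles_from_frames(
    profiles_df: pd.DataFrame, diagnoses_df: pd.DataFrame
) -> list[PatientProfile]:
    """Inverse of :func:`profiles_to_frame` / :func:`diagnoses_to_frame`."""
    diag: dict[str, set[str]] = {}
    for pid, group in diagnoses_df[["patient_id", "group"]].itertuples(index=False):
        diag.setdefault(pid, set()).add(group)
    out = []
    for row in profiles_df.itertuples(index=False):
        out.append(
            PatientProfile(
                patient_id=row.patient_id,
                age=float(getattr(row, "age", np.nan)),
                age_norm=float(row.age_norm),
                gender=int(row.gender),
                smoking=int(row.smoking),
                grouped_diagnoses=frozenset(diag.get(row.patient_id, set())),
                label=int(row.label),
            )
        )
    return out


def diagnoses_to_frame(profiles: list[PatientProfile]) -> pd.DataFrame:
    """Long-format (patient_id, group) table of grouped diagnoses."""
    rows = [
        {"patient_id": p.patient_id, "group": g}
        for p in profiles
        for g in sorted(p.grouped_diagnoses)
    ]
    return pd.DataFrame(rows, columns=["patient_id", "group"])
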