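"""Synthetic administrative-claims generator with planted comorbidity structure.

Real hospital claim data (patient ID, demographics, admission episodes, ICD
diagnosis codes) is rarely shareable, so every downstream stage of the
pipeline is exercised against synthetic claims generated here.  The generator
plants a simple block structure: a *case-enriched* block of diagnosis codes
(containing the target chronic disease), a *control-enriched* block of other
comorbidities, and a *shared background* block drawn by both groups.  Each
admission episode samples a block according to per-group probabilities and
then a code uniformly within the block, so shared-diagnosis edges in the
projected patient network concentrate within groups and case/control labels
become learnable from network structure alone.

Generation is a pure function of (spec, seed): identical inputs yield
byte-identical tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError

__all__ = [
    "SyntheticCohortSpec",
    "ClaimTable",
    "generate_claims",
    "inject_filter_violations",
    "DEFAULT_CASE_BLOCK",
    "DEFAULT_CONTROL_BLOCK",
    "DEFAULT_SHARED_BLOCK",
]

# Default code blocks. Case-enriched codes are cardiovascular (congestive
# heart failure, arrhythmia, pulmonary circulation and peripheral vascular
# disorders); control-enriched codes spread over ten non-cardiac comorbidity
# groups (diabetes, renal failure, liver disease, hypothyroidism, peptic
# ulcer, solid tumour, anemia, alcohol abuse, psychoses, epilepsy); the
# shared background holds comorbidities common to both groups (hypertension,
# obesity, depression, fluid/electrolyte disorders, coagulopathy, drug use).
# All codes resolve under the packaged comorbidity grouping table, so
# generated cohorts survive the episode-relevance filter by construction.
DEFAULT_CASE_BLOCK = (
    "I50.0", "I50.9", "I43.0", "I26.0", "I26.9", "I27.0", "I47.1",
    "I70.0", "I71.2", "I35.0", "428.0", "428.9", "427.31", "440.0", "441.2",
)
DEFAULT_CONTROL_BLOCK = (
    "E11.9", "E11.65", "250.00", "N18.3", "585.9", "K76.0", "571.8",
    "E03.9", "244.9", "M05.9", "714.0", "K27.9", "531.90",
    "C34.1", "162.9", "D50.9", "280.9", "F10.1", "303.90",
    "F20.0", "295.30", "G40.9", "345.9",
)
DEFAULT_SHARED_BLOCK = (
    "I10", "401.9", "E66.9", "278.00", "F32.9", "311", "E87.6", "276.8",
    "D68.9", "286.9", "F11.1", "304.00",
)

_SMOKING_CODE_ICD10 = "F17"
_SMOKING_CODE_ICD9 = "3051"


def _icd_version(code: str) -> int:
    """Infer the ICD version from the code shape (leading letter -> ICD-10)."""
    return 10 if code[:1].isalpha() else 9


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Parameters of a planted two-group synthetic claims cohort.

    ``block_probabilities`` maps each group ("case"/"control") to the
    probability that a single episode code is drawn from the case-enriched,
    control-enriched and shared background blocks respectively (must sum
    to 1).  ``episodes_per_patient`` stays inside the downstream admission
    filter window (at least 2, at most 50) so that, unless violations are
    injected deliberately, every generated patient survives filtering.
    """

    n_cases: int = 200
    n_controls: int = 200
    case_block: tuple[str, ...] = DEFAULT_CASE_BLOCK
    control_block: tuple[str, ...] = DEFAULT_CONTROL_BLOCK
    shared_block: tuple[str, ...] = DEFAULT_SHARED_BLOCK
    block_probabilities: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: {
            "case": (0.70, 0.05, 0.25),
            "control": (0.0, 0.70, 0.30),
        }
    )
    episodes_per_patient: tuple[int, int] = (2, 6)
    codes_per_episode: tuple[int, int] = (1, 2)
    age_range: tuple[int, int] = (40, 90)
    smoking_prevalence: dict[str, float] = field(
        default_factory=lambda: {"case": 0.45, "control": 0.15}
    )
    seed: int = 0

    def validate(self) -> None:
        if self.n_cases < 0:
            raise ConfigurationError(f"n_cases must be >= 0, got {self.n_cases}")
        if self.n_controls < 0:
            raise ConfigurationError(f"n_controls must be >= 0, got {self.n_controls}")
        if self.n_cases + self.n_controls == 0:
            raise ConfigurationError("n_cases + n_controls must be positive")
        for name, block in (
            ("case_block", self.case_block),
            ("control_block", self.control_block),
            ("shared_block", self.shared_block),
        ):
            if len(block) == 0:
                raise ConfigurationError(f"{name} must not be empty")
        for group in ("case", "control"):
            if group not in self.block_probabilities:
                raise ConfigurationError(f"block_probabilities missing group {group!r}")
            probs = self.block_probabilities[group]
            if len(probs) != 3 or any(p < 0 or p > 1 for p in probs):
                raise ConfigurationError(
                    f"block_probabilities[{group!r}] must be three values in [0,1]"
                )
            if abs(sum(probs) - 1.0) > 1e-9:
                raise ConfigurationError(
                    f"block_probabilities[{group!r}] must sum to 1, got {sum(probs)}"
                )
            prev = self.smoking_prevalence.get(group)
            if prev is None or not (0.0 <= prev <= 1.0):
                raise ConfigurationError(
                    f"smoking_prevalence[{group!r}] must be in [0,1]"
                )
        lo, hi = self.episodes_per_patient
        if not (2 <= lo <= hi <= 50):
            raise ConfigurationError(
                f"episodes_per_patient must satisfy 2 <= min <= max <= 50, got {lo, hi}"
            )
        clo, chi = self.codes_per_episode
        if not (1 <= clo <= chi):
            raise ConfigurationError(
                f"codes_per_episode must satisfy 1 <= min <= max, got {clo, chi}"
            )
        alo, ahi = self.age_range
        if not (0 < alo <= ahi):
            raise ConfigurationError(f"age_range must be positive, got {alo, ahi}")


@dataclass
class ClaimTable:
    """Claims in long format plus hidden per-patient ground truth.

    ``claims`` columns: patient_id, age, gender, episode_id, icd_version,
    icd_code.  ``truth`` columns: patient_id, label (1 = planted case),
    must_filter (True for injected filter-violation patients).  Ground truth
    lives outside the claim columns so the pipeline cannot leak it.
    """

    claims: pd.DataFrame
    truth: pd.DataFrame

    def labels(self) -> pd.Series:
        """Per-patient planted label indexed by patient_id."""
        return self.truth.set_index("patient_id")["label"]

    def write(self, claims_path: str | Path, labels_path: str | Path) -> None:
        self.claims.to_csv(claims_path, index=False)
        self.truth[["patient_id", "label"]].to_csv(labels_path, index=False)


def _blocks(spec: SyntheticCohortSpec) -> list[tuple[str, ...]]:
    return [spec.case_block, spec.control_block, spec.shared_block]


def _sample_patient_rows(
    rng: np.random.Generator,
    spec: SyntheticCohortSpec,
    patient_id: str,
    group: str,
) -> list[dict]:
    blocks = _blocks(spec)
    probs = np.asarray(spec.block_probabilities[group], dtype=float)
    age = int(rng.integers(spec.age_range[0], spec.age_range[1] + 1))
    gender = int(rng.integers(0, 2))
    smoker = bool(rng.random() < spec.smoking_prevalence[group])
    n_episodes = int(
        rng.integers(spec.episodes_per_patient[0], spec.episodes_per_patient[1] + 1)
    )
    rows: list[dict] = []
    for ep in range(1, n_episodes + 1):
        episode_id = f"{patient_id}-E{ep:02d}"
        n_codes = int(
            rng.integers(spec.codes_per_episode[0], spec.codes_per_episode[1] + 1)
        )
        seen: set[str] = set()
        for _ in range(n_codes):
            block = blocks[int(rng.choice(3, p=probs))]
            code = block[int(rng.integers(0, len(block)))]
            if code in seen:
                continue
            seen.add(code)
            rows.append(
                {
                    "patient_id": patient_id,
                    "age": age,
                    "gender": gender,
                    "episode_id": episode_id,
                    "icd_version": _icd_version(code),
                    "icd_code": code,
                }
            )
    if smoker:
        # Attach one smoking diagnosis to a random episode of the patient.
        ep = int(rng.integers(1, n_episodes + 1))
        code = _SMOKING_CODE_ICD10 if rng.random() < 0.5 else _SMOKING_CODE_ICD9
        rows.append(
            {
                "patient_id": patient_id,
                "age": age,
                "gender": gender,
                "episode_id": f"{patient_id}-E{ep:02d}",
                "icd_version": _icd_version(code),
                "icd_code": code,
            }
        )
    return rows


def generate_claims(spec: SyntheticCohortSpec) -> ClaimTable:
    """Generate a planted case/control claims cohort.

    Returns ``spec.n_cases + spec.n_controls`` patients; cases draw codes
    preferentially from the case-enriched block so shared-diagnosis edge
    weight concentrates within groups.  Deterministic under ``spec.seed``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    rows: list[dict] = []
    truth: list[dict] = []
    total = spec.n_cases + spec.n_controls
    width = max(4, len(str(total)))
    for i in range(total):
        group = "case" if i < spec.n_cases else "control"
        patient_id = f"P{i + 1:0{width}d}"
        rows.extend(_sample_patient_rows(rng, spec, patient_id, group))
        truth.append(
            {
                "patient_id": patient_id,
                "label": 1 if group == "case" else 0,
                "must_filter": False,
            }
        )
    claims = pd.DataFrame(
        rows,
        columns=["patient_id", "age", "gender", "episode_id", "icd_version", "icd_code"],
    )
    return ClaimTable(claims=claims, truth=pd.DataFrame(truth))


def inject_filter_violations(
    table: ClaimTable, n_single_episode: int, n_over_cap: int, seed: int = 0
) -> ClaimTable:
    """Append patients that violate the admission-count filters.

    Adds ``n_single_episode`` patients with exactly one admission episode and
    ``n_over_cap`` patients with more than 50 episodes, all flagged
    ``must_filter`` in the ground truth.  Their codes come from the shared
    background block, so only the episode-count criteria can remove them.
    """
    if n_single_episode < 0 or n_over_cap < 0:
        raise ConfigurationError("violation counts must be >= 0")
    if table.claims.empty:
        raise ConfigurationError("cannot inject violations into an empty table")
    if n_single_episode == 0 and n_over_cap == 0:
        return table
    rng = np.random.default_rng(seed)
    shared = DEFAULT_SHARED_BLOCK
    rows: list[dict] = []
    truth: list[dict] = []

    def add_patient(pid: str, n_episodes: int) -> None:
        age = int(rng.integers(40, 91))
        gender = int(rng.integers(0, 2))
        for ep in range(1, n_episodes + 1):
            code = shared[int(rng.integers(0, len(shared)))]
            rows.append(
                {
                    "patient_id": pid,
                    "age": age,
                    "gender": gender,
                    "episode_id": f"{pid}-E{ep:03d}",
                    "icd_version": _icd_version(code),
                    "icd_code": code,
                }
            )
        truth.append({"patient_id": pid, "label": 0, "must_filter": True})

    for i in range(n_single_episode):
        add_patient(f"XS{i + 1:04d}", 1)
    for i in range(n_over_cap):
        add_patient(f"XO{i + 1:04d}", int(rng.integers(51, 61)))

    claims = pd.concat([table.claims, pd.DataFrame(rows)], ignore_index=True)
    new_truth = pd.concat([table.truth, pd.DataFrame(truth)], ignore_index=True)
    return ClaimTable(claims=claims, truth=new_truth)


def spec_from_dict(d: dict) -> SyntheticCohortSpec:
    """Build a spec from a plain (e.g. YAML-loaded) mapping."""
    kwargs = dict(d)
    for key in ("case_block", "control_block", "shared_block"):
        if key in kwargs:
            kwargs[key] = tuple(kwargs[key])
    for key in ("episodes_per_patient", "codes_per_episode", "age_range"):
        if key in kwargs:
            kwargs[key] = tuple(kwargs[key])
    if "block_probabilities" in kwargs:
        kwargs["block_probabilities"] = {
            g: tuple(p) for g, p in kwargs["block_probabilities"].items()
        }
    unknown = set(kwargs) - set(SyntheticCohortSpec.__dataclass_fields__)
    if unknown:
        raise ConfigurationError(f"unknown cohort spec fields: {sorted(unknown)}")
    try:
        spec = SyntheticCohortSpec(**kwargs)
    except TypeError as exc:  # pragma: no cover - defensive
        raise ConfigurationError(str(exc)) from exc
    spec.validate()
    return spec
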