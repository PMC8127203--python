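"""Synthetic cohort and claims generator for juvenile arthritis (JA) case
ascertainment studies.

The generator emulates the structure of linked administrative health data:
a two-group cohort (JA cases and non-JA controls referred to a pediatric
rheumatology clinic), four annual healthcare-utilization measures observed on
15 occasions from birth to the 16th birthday, and the dated physician claims
and hospital discharge abstracts those measures are derived from.

Measures are drawn from Bernoulli-logit / Poisson-log models with a
per-marker random intercept; default generating parameters are the posterior
means of the fitted full utilization model (separate parameters per group).
Claims are then emitted so that re-deriving the annual measures from them
reproduces the measure matrix exactly, which makes the deterministic ICD
case definition exercisable on the same synthetic individuals.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import asdict, dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit

from .grid import DEFAULT_GRID, OccasionGrid

# ---------------------------------------------------------------------------
# markers

MARKER_ORDER = ("ja_contact", "gp_visits", "specialist_visits", "hospitalization")
FAMILY_BY_MARKER = {
    "ja_contact": "bernoulli_logit",
    "gp_visits": "poisson_log",
    "specialist_visits": "poisson_log",
    "hospitalization": "bernoulli_logit",
}

# ---------------------------------------------------------------------------
# ICD code sets

#: ICD-9-CM categories counting as a JA-related healthcare contact.
JA_CONTACT_ICD9 = ("696", "713", "714", "716", "720")
#: ICD-10-CA roots: M05-M09 (inclusive range) and M45.
JA_CONTACT_ICD10_LO = "M05"
JA_CONTACT_ICD10_HI = "M09"
JA_CONTACT_ICD10_EXTRA = ("M45",)


def is_ja_related(code: str, icd_version: int) -> bool:
    """True iff the code's leading category is a JA-related contact code.

    Matching is prefix-based on the category (3-character ICD-9 root;
    letter + 2 digits ICD-10 root) because administrative data record codes
    at four or more characters.
    """
    if icd_version not in (9, 10):
        raise ValueError(f"icd_version must be 9 or 10, got {icd_version!r}")
    code = str(code).strip().upper()
    if not code:
        raise ValueError("empty diagnosis code")
    root = code[:3]
    if icd_version == 9:
        return root in JA_CONTACT_ICD9
    if root in JA_CONTACT_ICD10_EXTRA:
        return True
    return JA_CONTACT_ICD10_LO <= root <= JA_CONTACT_ICD10_HI and root.startswith("M0")


# ---------------------------------------------------------------------------
# records


@dataclass(frozen=True)
class ClaimRecord:
    """One dated healthcare contact: a physician claim or hospital abstract."""

    person_id: object
    day: int
    record_type: str  # physician | hospital
    provider_class: str  # GP | specialist | none (none iff hospital)
    setting: str  # ambulatory | inpatient
    icd_version: int
    diagnosis_codes: tuple[str, ...]
    newborn_flag: bool = False

    def validate(self) -> None:
        from .grid import MAX_DAY

        if not (0 <= self.day < MAX_DAY):
            raise ValueError(f"claim day {self.day} outside [0, {MAX_DAY})")
        if self.record_type == "physician":
            if len(self.diagnosis_codes) != 1:
                raise ValueError("physician claims carry exactly one diagnosis code")
            if self.provider_class not in ("GP", "specialist"):
                raise ValueError("physician claims need a GP/specialist provider class")
            if self.newborn_flag:
                raise ValueError("newborn_flag applies to hospital records only")
        elif self.record_type == "hospital":
            if not (1 <= len(self.diagnosis_codes) <= 25):
                raise ValueError("hospital abstracts carry 1..25 diagnosis codes")
            if self.provider_class != "none":
                raise ValueError("hospital records have no provider class")
        else:
            raise ValueError(f"unknown record_type {self.record_type!r}")
        if self.icd_version not in (9, 10):
            raise ValueError("icd_version must be 9 or 10")
        if self.setting not in ("ambulatory", "inpatient"):
            raise ValueError(f"unknown setting {self.setting!r}")


@dataclass
class IndividualRecord:
    """Covariates, occasion-by-marker measure matrix and gold-standard label."""

    person_id: object
    sex: str  # male | female
    region: str  # urban | rural
    income_quintile: int
    group: str  # case | control  (gold standard)
    measures: np.ndarray  # (n_occasions, 4) ints, columns in MARKER_ORDER
    latent_intercepts: dict[str, float] | None = None  # generator truth


# ---------------------------------------------------------------------------
# generating parameters


@dataclass(frozen=True)
class MarkerParams:
    """Generating parameters for one marker: fixed effects on the link scale
    plus the random-intercept distribution N(intercept_mean, intercept_sd^2)."""

    male: float
    urban: float
    age: float
    intercept_mean: float
    intercept_sd: float


def default_case_params() -> dict[str, MarkerParams]:
    """Full utilization model posterior means, JA cases."""
    return {
        "ja_contact": MarkerParams(-0.59, -0.24, 0.21, -1.77, 1.60),
        "gp_visits": MarkerParams(0.03, -0.50, -0.11, 1.62, 0.94),
        "specialist_visits": MarkerParams(-0.19, 0.55, -0.04, 1.26, 0.80),
        "hospitalization": MarkerParams(0.24, -0.57, -0.11, -1.46, 0.87),
    }


def default_control_params() -> dict[str, MarkerParams]:
    """Full utilization model posterior means, non-JA controls."""
    return {
        "ja_contact": MarkerParams(-0.07, -0.53, 0.17, -4.74, 1.03),
        "gp_visits": MarkerParams(-0.02, -0.46, -0.10, 1.45, 1.00),
        "specialist_visits": MarkerParams(-0.13, 0.63, -0.03, 0.91, 0.92),
        "hospitalization": MarkerParams(0.02, -0.58, -0.04, -1.47, 0.84),
    }


def _default_ja_code_weights() -> dict:
    # Mix of specific diagnosis categories carried on JA-related contacts.
    # Cases are mostly coded to rheumatoid arthritis / ankylosing spondylitis
    # categories (the codes the validated deterministic definition looks for);
    # controls seen by a rheumatologist mostly carry other arthropathy codes.
    return {
        "case": {
            9: {"714": 0.60, "720": 0.15, "716": 0.15, "713": 0.05, "696": 0.05},
            10: {"M08": 0.60, "M45": 0.15, "M06": 0.10, "M09": 0.10, "M07": 0.05},
        },
        "control": {
            9: {"716": 0.45, "713": 0.25, "696": 0.20, "714": 0.05, "720": 0.05},
            10: {"M09": 0.40, "M07": 0.40, "M06": 0.05, "M08": 0.10, "M45": 0.05},
        },
    }


_NONJA_PHYSICIAN_ICD9 = ("4659", "38200", "V202", "486", "5589", "7806")
_NONJA_HOSPITAL_CODES = {9: ("486", "5589", "8472"), 10: ("J189", "A099", "S7200")}
_NEWBORN_CODE = {9: "V3000", 10: "Z380"}


@dataclass
class GeneratorConfig:
    """Study-condition defaults for the synthetic cohort.

    Cohort composition follows the referral cohort the generator emulates:
    797 children, 48.4% JA cases, ~65% female, ~57% urban at birth.
    """

    n_individuals: int = 797
    case_fraction: float = 0.484
    p_female: float = 0.65
    p_urban: float = 0.57
    case_params: dict[str, MarkerParams] = field(default_factory=default_case_params)
    control_params: dict[str, MarkerParams] = field(default_factory=default_control_params)
    #: probability a JA-coded physician claim is placed on a specialist visit
    ja_specialist_prob: float = 0.8
    #: mean extra JA-coded claims beyond the first in a contact year (Poisson)
    extra_ja_claims_mean: float = 1.0
    #: probability a hospital abstract in a JA-contact year also carries a JA code
    hospital_ja_code_prob: float = 0.5
    #: probability a hospital abstract is coded in ICD-10 rather than ICD-9
    hospital_icd10_prob: float = 0.5
    #: probability a newborn (birth) hospital record is emitted
    newborn_record_prob: float = 0.98
    ja_code_weights: dict = field(default_factory=_default_ja_code_weights)
    seed: int = 0

    def validate(self) -> None:
        if self.n_individuals < 0:
            raise ValueError("n_individuals must be non-negative")
        for name, p in [
            ("case_fraction", self.case_fraction),
            ("p_female", self.p_female),
            ("p_urban", self.p_urban),
            ("ja_specialist_prob", self.ja_specialist_prob),
            ("hospital_ja_code_prob", self.hospital_ja_code_prob),
            ("hospital_icd10_prob", self.hospital_icd10_prob),
            ("newborn_record_prob", self.newborn_record_prob),
        ]:
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        if self.extra_ja_claims_mean < 0:
            raise ValueError("extra_ja_claims_mean must be >= 0")
        for params in (self.case_params, self.control_params):
            for marker, mp in params.items():
                vals = (mp.male, mp.urban, mp.age, mp.intercept_mean, mp.intercept_sd)
                if not np.all(np.isfinite(vals)):
                    raise ValueError(f"non-finite generating parameters for {marker}")
                if mp.intercept_sd < 0:
                    raise ValueError(f"negative intercept SD for {marker}")


# ---------------------------------------------------------------------------
# cohort generation


def generate_cohort(
    config: GeneratorConfig, grid: OccasionGrid = DEFAULT_GRID
) -> list[IndividualRecord]:
    """Draw a synthetic two-group cohort of measure-level records.

    Group labels, covariates and per-marker latent intercepts are drawn
    independently; measures come from the group's Bernoulli-logit /
    Poisson-log model with linear predictor
    ``male*a_m + urban*a_u + age_j*a_t + b`` per occasion.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_individuals
    if n == 0:
        return []

    is_case = rng.random(n) < config.case_fraction
    female = rng.random(n) < config.p_female
    urban = rng.random(n) < config.p_urban
    income = rng.integers(1, 6, size=n)
    male = (~female).astype(float)
    urb = urban.astype(float)
    ages = grid.covariate_ages
    J = grid.n_occasions

    measures = np.zeros((n, J, len(MARKER_ORDER)), dtype=np.int64)
    intercepts = np.zeros((n, len(MARKER_ORDER)))
    for flag, params in ((True, config.case_params), (False, config.control_params)):
        idx = np.flatnonzero(is_case == flag)
        if idx.size == 0:
            continue
        for r, marker in enumerate(MARKER_ORDER):
            mp = params[marker]
            b = rng.normal(mp.intercept_mean, mp.intercept_sd, size=idx.size)
            intercepts[idx, r] = b
            eta = (
                mp.male * male[idx, None]
                + mp.urban * urb[idx, None]
                + mp.age * ages[None, :]
                + b[:, None]
            )
            if FAMILY_BY_MARKER[marker] == "bernoulli_logit":
                y = (rng.random((idx.size, J)) < expit(eta)).astype(np.int64)
            else:
                y = rng.poisson(np.exp(eta)).astype(np.int64)
            measures[idx, :, r] = y

    cohort = []
    for i in range(n):
        cohort.append(
            IndividualRecord(
                person_id=i + 1,
                sex="female" if female[i] else "male",
                region="urban" if urban[i] else "rural",
                income_quintile=int(income[i]),
                group="case" if is_case[i] else "control",
                measures=measures[i].copy(),
                latent_intercepts={
                    m: float(intercepts[i, r]) for r, m in enumerate(MARKER_ORDER)
                },
            )
        )
    return cohort


# ---------------------------------------------------------------------------
# claims generation


def _person_rng(config: GeneratorConfig, person_id) -> np.random.Generator:
    tag = zlib.crc32(str(person_id).encode())
    return np.random.default_rng([config.seed, tag])


def _draw_code(rng: np.random.Generator, weights: dict[str, float]) -> str:
    cats = sorted(weights)
    w = np.array([weights[c] for c in cats], dtype=float)
    cat = cats[int(rng.choice(len(cats), p=w / w.sum()))]
    return cat + str(int(rng.integers(0, 10)))


def generate_claims(
    individual: IndividualRecord,
    config: GeneratorConfig,
    grid: OccasionGrid = DEFAULT_GRID,
    rng: np.random.Generator | None = None,
) -> list[ClaimRecord]:
    """Emit dated claims exactly consistent with the individual's measures.

    Per occasion: the counts of ambulatory GP / specialist claims equal the
    recorded visit counts; at least one record carries a JA-related code iff
    the contact indicator is 1; a non-newborn hospital abstract exists iff
    the hospitalization indicator is 1. Claim days are uniform within the
    occasion's age span. Physician claims are always ICD-9 (the claims system
    codes a single ICD-9 diagnosis); hospital abstracts are ICD-9 or ICD-10.
    """
    if individual.measures is None:
        raise ValueError("individual has no measures")
    M = np.asarray(individual.measures)
    if M.shape != (grid.n_occasions, len(MARKER_ORDER)):
        raise ValueError(f"measure matrix must be {grid.n_occasions}x{len(MARKER_ORDER)}")
    if np.any(M < 0):
        raise ValueError("measure matrix contains negative counts")
    if rng is None:
        rng = _person_rng(config, individual.person_id)

    pid = individual.person_id
    group = individual.group if individual.group in ("case", "control") else "control"
    w9 = config.ja_code_weights[group][9]
    w10 = config.ja_code_weights[group][10]

    claims: list[ClaimRecord] = []
    for occ in grid.occasions:
        ja, gp, sp, ho = (int(v) for v in M[occ.index - 1])

        def _day():
            return int(rng.integers(occ.day_lo, occ.day_hi))

        phys: list[ClaimRecord] = []
        for provider, count in (("GP", gp), ("specialist", sp)):
            for _ in range(count):
                code = _NONJA_PHYSICIAN_ICD9[int(rng.integers(len(_NONJA_PHYSICIAN_ICD9)))]
                phys.append(
                    ClaimRecord(pid, _day(), "physician", provider, "ambulatory", 9, (code,))
                )

        hosp_codes: list[str] | None = None
        hosp_version = 9
        hosp_day = 0
        if ho:
            hosp_version = 10 if rng.random() < config.hospital_icd10_prob else 9
            pool = _NONJA_HOSPITAL_CODES[hosp_version]
            n_codes = int(rng.integers(1, 4))
            hosp_codes = [pool[int(rng.integers(len(pool)))] for _ in range(n_codes)]
            hosp_day = _day()

        if ja:
            n_ja = 1 + int(rng.poisson(config.extra_ja_claims_mean))
            spec_pool = [i for i, c in enumerate(phys) if c.provider_class == "specialist"]
            gp_pool = [i for i, c in enumerate(phys) if c.provider_class == "GP"]
            assigned = 0
            while assigned < n_ja and (spec_pool or gp_pool):
                use_spec = bool(spec_pool) and (
                    not gp_pool or rng.random() < config.ja_specialist_prob
                )
                pool_ = spec_pool if use_spec else gp_pool
                k = pool_.pop(int(rng.integers(len(pool_))))
                phys[k] = replace(phys[k], diagnosis_codes=(_draw_code(rng, w9),))
                assigned += 1
            if hosp_codes is not None and (
                assigned == 0 or rng.random() < config.hospital_ja_code_prob
            ):
                hosp_codes.append(_draw_code(rng, w10 if hosp_version == 10 else w9))
                assigned += 1
            if assigned == 0:
                # no ambulatory visit or hospital stay to carry the diagnosis:
                # an in-hospital / ER physician consult claim does
                phys.append(
                    ClaimRecord(
                        pid, _day(), "physician", "specialist", "inpatient", 9,
                        (_draw_code(rng, w9),),
                    )
                )

        claims.extend(phys)
        if hosp_codes is not None:
            claims.append(
                ClaimRecord(
                    pid, hosp_day, "hospital", "none", "inpatient",
                    hosp_version, tuple(hosp_codes[:25]),
                )
            )

    if rng.random() < config.newborn_record_prob:
        version = 10 if rng.random() < config.hospital_icd10_prob else 9
        claims.append(
            ClaimRecord(
                pid, int(rng.integers(0, 4)), "hospital", "none", "inpatient",
                version, (_NEWBORN_CODE[version],), newborn_flag=True,
            )
        )
    return claims


def generate_claims_for_cohort(
    cohort: list[IndividualRecord],
    config: GeneratorConfig,
    grid: OccasionGrid = DEFAULT_GRID,
) -> dict:
    """Claims for every individual, keyed by person id (deterministic per config)."""
    return {ind.person_id: generate_claims(ind, config, grid) for ind in cohort}


# ---------------------------------------------------------------------------
# measure derivation


def derive_annual_measures(
    claims: list[ClaimRecord], grid: OccasionGrid = DEFAULT_GRID
) -> np.ndarray:
    """Aggregate one person's claims into the occasion-by-marker matrix.

    Per occasion: any record (physician claim or any hospital diagnosis)
    carrying a JA-related code sets the contact indicator; ambulatory
    physician claims are counted by provider class; any non-newborn hospital
    abstract sets the hospitalization indicator.
    """
    M = np.zeros((grid.n_occasions, len(MARKER_ORDER)), dtype=np.int64)
    for c in claims:
        row = grid.occasion_of_day(c.day) - 1
        ja_coded = any(is_ja_related(code, c.icd_version) for code in c.diagnosis_codes)
        if c.record_type == "physician":
            if ja_coded:
                M[row, 0] = 1
            if c.setting == "ambulatory":
                if c.provider_class == "GP":
                    M[row, 1] += 1
                elif c.provider_class == "specialist":
                    M[row, 2] += 1
        elif c.record_type == "hospital":
            if ja_coded:
                M[row, 0] = 1
            if not c.newborn_flag:
                M[row, 3] = 1
        else:
            raise ValueError(f"unknown record_type {c.record_type!r}")
    return M


# ---------------------------------------------------------------------------
# external interfaces (CSV)

_MAX_CODES = 25


def claims_to_frame(claims_by_person: dict) -> pd.DataFrame:
    rows = []
    for pid, claims in claims_by_person.items():
        for c in claims:
            row = {
                "person_id": pid,
                "day": c.day,
                "record_type": c.record_type,
                "provider_class": c.provider_class,
                "setting": c.setting,
                "icd_version": c.icd_version,
                "newborn_flag": c.newborn_flag,
            }
            for k in range(_MAX_CODES):
                row[f"code_{k + 1}"] = (
                    c.diagnosis_codes[k] if k < len(c.diagnosis_codes) else ""
                )
            rows.append(row)
    return pd.DataFrame(rows)


def frame_to_claims(df: pd.DataFrame) -> dict:
    code_cols = [c for c in df.columns if c.startswith("code_")]
    out: dict = {}
    for row in df.itertuples(index=False):
        d = row._asdict()
        codes = tuple(
            str(d[c]) for c in code_cols if str(d[c]) not in ("", "nan", "None")
        )
        rec = ClaimRecord(
            person_id=d["person_id"],
            day=int(d["day"]),
            record_type=str(d["record_type"]),
            provider_class=str(d["provider_class"]),
            setting=str(d["setting"]),
            icd_version=int(d["icd_version"]),
            diagnosis_codes=codes,
            newborn_flag=bool(d["newborn_flag"]),
        )
        out.setdefault(rec.person_id, []).append(rec)
    return out


def cohort_to_frame(cohort: list[IndividualRecord], grid: OccasionGrid = DEFAULT_GRID) -> pd.DataFrame:
    rows = []
    for ind in cohort:
        row = {
            "person_id": ind.person_id,
            "sex": ind.sex,
            "region": ind.region,
            "income_quintile": ind.income_quintile,
            "group": ind.group,
        }
        for r, marker in enumerate(MARKER_ORDER):
            for j in range(grid.n_occasions):
                row[f"{marker}_occ{j + 1}"] = int(ind.measures[j, r])
        rows.append(row)
    return pd.DataFrame(rows)


def frame_to_cohort(df: pd.DataFrame, grid: OccasionGrid = DEFAULT_GRID) -> list[IndividualRecord]:
    cohort = []
    J = grid.n_occasions
    for row in df.to_dict("records"):
        M = np.zeros((J, len(MARKER_ORDER)), dtype=np.int64)
        for r, marker in enumerate(MARKER_ORDER):
            for j in range(J):
                M[j, r] = int(row[f"{marker}_occ{j + 1}"])
        cohort.append(
            IndividualRecord(
                person_id=row["person_id"],
                sex=str(row["sex"]),
                region=str(row["region"]),
                income_quintile=int(row["income_quintile"]),
                group=str(row["group"]),
                measures=M,
            )
        )
    return cohort


def truth_to_frame(cohort: list[IndividualRecord]) -> pd.DataFrame:
    rows = []
    for ind in cohort:
        row = {"person_id": ind.person_id, "group": ind.group}
        if ind.latent_intercepts:
            for m in MARKER_ORDER:
                row[f"b_{m}"] = ind.latent_intercepts.get(m, np.nan)
        rows.append(row)
    return pd.DataFrame(rows)


def config_to_json(config: GeneratorConfig) -> str:
    d = asdict(config)
    d["ja_code_weights"] = {
        g: {str(v): w for v, w in versions.items()}
        for g, versions in d["ja_code_weights"].items()
    }
    return json.dumps(d, indent=2)
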