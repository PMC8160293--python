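"""Surveillance case definitions for recurrent TBI in administrative claims.

Four binary case definitions are applied to each patient's claim stream in
a fixed window after the index TBI (by default days 7-365, because claims
in the first week are attributed to the index event):

1. ``outpatient``  - a physician claim with a TBI diagnostic code billed in
   the outpatient setting;
2. ``er``          - a physician claim with a TBI diagnostic code billed in
   the emergency department;
3. ``dad``         - any TBI diagnostic code in the hospital discharge
   abstract database (DAD), primary or secondary;
4. ``radiology``   - a billing claim for a radiological examination of the
   head (CT/MRI/skull x-ray billing codes) together with a physician claim
   carrying *any* trauma diagnosis, the two dated within one day of each
   other.

Hospital (inpatient) physician claims are parsed and validated but do not
feed any definition; they identify index-event care, not recurrence.

The joint outcome of the four definitions for one patient is a response
pattern, one of 2^4 = 16 possibilities; the pattern counts are the
sufficient statistic for the two-class latent class model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ArgumentError, EmptyInputError, ValidationError

#: Case-definition names in fixed bit order (most significant bit first).
DEFINITIONS = ("outpatient", "er", "dad", "radiology")

#: Recognised claim sources.
CLAIM_SOURCES = (
    "outpatient",
    "emergency",
    "hospital_physician",
    "dad",
    "radiology_billing",
)

#: Physician-claim sources eligible to carry the trauma diagnosis that
#: pairs with a radiology billing claim.
PHYSICIAN_SOURCES = ("outpatient", "emergency", "hospital_physician")

#: Recognised coding systems.
CODE_SYSTEMS = ("ICD9", "ICD10", "billing")

# Default TBI diagnostic code families, as prefixes on dot-stripped codes.
# These follow widely used TBI surveillance definitions (skull fracture,
# intracranial injury, injury to optic pathways, concussion sequelae) and
# are overridable per definition.
DEFAULT_ICD9_TBI_PREFIXES = (
    "800", "801", "802", "803", "804",
    "850", "851", "852", "853", "854",
    "9501", "9502", "9503", "95901",
)
DEFAULT_ICD10_TBI_PREFIXES = (
    "S02", "S06", "S07", "S097", "S098", "S099", "T902", "T905",
)

#: Any-trauma ICD-9 families (8XX, 91X, 92X, 93X) matched as prefixes.
DEFAULT_TRAUMA_PREFIXES = ("8", "91", "92", "93")

#: Head-imaging billing codes (CT brain, MRI brain, skull x-ray).
DEFAULT_RADIOLOGY_CODES = ("08258", "08259", "08570", "08010", "08013")


def normalize_code(code: str) -> str:
    """Normalize a diagnostic/billing code: strip dots and whitespace, uppercase."""
    return str(code).replace(".", "").strip().upper()


@dataclass(frozen=True)
class AscertainmentWindow:
    """Post-index window, in days, within which claims count as recurrence."""

    min_day: int = 7
    max_day: int = 365

    def __post_init__(self) -> None:
        if not (0 < self.min_day < self.max_day):
            raise ArgumentError(
                f"require 0 < min_day < max_day, got ({self.min_day}, {self.max_day})"
            )


@dataclass(frozen=True)
class CaseDefinitionSpec:
    """One surveillance case definition over claim streams.

    ``sources`` restricts which claim sources can satisfy the definition.
    ``icd9_prefixes``/``icd10_prefixes`` are matched as string prefixes on
    normalized codes. The radiology definition additionally needs
    ``radiology_billing_codes`` (exact match) and ``trauma_code_prefixes``
    for its paired physician claim, with the pair dated within
    ``pairing_window_days`` of each other.
    """

    name: str
    sources: tuple[str, ...]
    icd9_prefixes: tuple[str, ...] = DEFAULT_ICD9_TBI_PREFIXES
    icd10_prefixes: tuple[str, ...] = DEFAULT_ICD10_TBI_PREFIXES
    trauma_code_prefixes: tuple[str, ...] = DEFAULT_TRAUMA_PREFIXES
    radiology_billing_codes: tuple[str, ...] = DEFAULT_RADIOLOGY_CODES
    pairing_window_days: int = 1

    def __post_init__(self) -> None:
        if self.name == "radiology":
            if not self.radiology_billing_codes or not self.trauma_code_prefixes:
                raise ArgumentError(
                    "radiology definition needs billing codes and trauma prefixes"
                )
        elif not (self.icd9_prefixes or self.icd10_prefixes):
            raise ArgumentError(f"definition {self.name!r} has empty code lists")


def default_specs() -> tuple[CaseDefinitionSpec, ...]:
    """The four default case definitions in bit order."""
    return (
        CaseDefinitionSpec("outpatient", sources=("outpatient",)),
        CaseDefinitionSpec("er", sources=("emergency",)),
        CaseDefinitionSpec("dad", sources=("dad",)),
        CaseDefinitionSpec("radiology", sources=("radiology_billing",)),
    )


def pattern_matrix(n_definitions: int = 4) -> np.ndarray:
    """(2^J, J) binary matrix: row ``i`` is the flags of pattern index ``i``.

    Bit order is most-significant-first, so for four definitions row
    ``0b1001`` is ``(1, 0, 0, 1)`` = (outpatient, er, dad, radiology).
    """
    n = 2**n_definitions
    idx = np.arange(n)
    return (idx[:, None] >> np.arange(n_definitions - 1, -1, -1)[None, :]) & 1


def pattern_index(flags) -> int:
    """Inverse of :func:`pattern_matrix`: flags (MSB first) -> pattern index."""
    flags = np.asarray(flags, dtype=int)
    return int(flags @ (2 ** np.arange(len(flags) - 1, -1, -1)))


@dataclass
class ResponsePatternCounts:
    """Counts of the 2^J case-definition response patterns in one cohort."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        n = len(self.counts)
        if n < 2 or n & (n - 1):
            raise ArgumentError(f"counts length must be a power of two, got {n}")
        if (self.counts < 0).any():
            raise ArgumentError("pattern counts must be non-negative")

    @property
    def n_definitions(self) -> int:
        return int(np.log2(len(self.counts)))

    @property
    def n(self) -> int:
        """Cohort size (sum of counts)."""
        return int(self.counts.sum())

    @classmethod
    def from_flags(cls, flags) -> "ResponsePatternCounts":
        """Aggregate an (n, J) boolean flag array into pattern counts."""
        flags = np.asarray(flags, dtype=int)
        j = flags.shape[1]
        idx = flags @ (2 ** np.arange(j - 1, -1, -1))
        return cls(np.bincount(idx, minlength=2**j))


def _validate_claims(claims: pd.DataFrame) -> None:
    bad_source = ~claims["source"].isin(CLAIM_SOURCES)
    bad_system = ~claims["code_system"].isin(CODE_SYSTEMS)
    if bad_source.any() or bad_system.any():
        rows = claims.index[bad_source | bad_system][:10].tolist()
        raise ValidationError(
            f"claims with unknown source/code_system at rows {rows} "
            f"(sources must be one of {CLAIM_SOURCES}, "
            f"systems one of {CODE_SYSTEMS})"
        )


def _tbi_code_mask(codes: pd.Series, systems: pd.Series, spec: CaseDefinitionSpec) -> np.ndarray:
    """Prefix-match normalized codes against the spec's ICD-9/ICD-10 lists."""
    norm = codes.map(normalize_code)
    m9 = norm.str.startswith(spec.icd9_prefixes) & (systems == "ICD9")
    m10 = norm.str.startswith(spec.icd10_prefixes) & (systems == "ICD10")
    return (m9 | m10).to_numpy()


def apply_case_definitions(
    claims: pd.DataFrame,
    index_episodes: pd.DataFrame,
    specs: tuple[CaseDefinitionSpec, ...] | None = None,
    window: AscertainmentWindow | None = None,
) -> pd.DataFrame:
    """Apply the four case definitions to each patient's post-index claims.

    Parameters
    ----------
    claims
        Columns ``patient_id, service_date, source, code, code_system``.
    index_episodes
        One row per patient at risk: ``patient_id, index_date``. Patients
        with no claims still appear in the output with all flags False.
    specs, window
        Override the default definitions / days 7-365 window.

    Returns
    -------
    DataFrame with one row per index episode: ``patient_id``, a boolean
    column per definition (bit order ``outpatient, er, dad, radiology``),
    and ``first_hit_day`` (days since index of the earliest qualifying
    claim across met definitions; the radiology definition's day is the
    day of the imaging claim). Claims earlier than ``index + min_day`` are
    attributed to the index event and ignored.
    """
    specs = default_specs() if specs is None else specs
    window = AscertainmentWindow() if window is None else window
    if len(index_episodes) == 0:
        raise EmptyInputError("no index episodes supplied")
    _validate_claims(claims)

    df = claims.merge(
        index_episodes[["patient_id", "index_date"]], on="patient_id", how="inner"
    )
    df["day"] = (
        pd.to_datetime(df["service_date"]) - pd.to_datetime(df["index_date"])
    ).dt.days
    in_window = (df["day"] >= window.min_day) & (df["day"] <= window.max_day)

    first_days: dict[str, pd.Series] = {}
    for spec in specs:
        if spec.name == "radiology":
            first_days[spec.name] = _radiology_first_days(df, spec, in_window)
        else:
            mask = (
                df["source"].isin(spec.sources)
                & in_window
                & _tbi_code_mask(df["code"], df["code_system"], spec)
            )
            first_days[spec.name] = df.loc[mask].groupby("patient_id")["day"].min()

    hits = index_episodes[["patient_id"]].copy()
    day_cols = []
    for spec in specs:
        days = hits["patient_id"].map(first_days[spec.name])
        hits[spec.name] = days.notna()
        day_cols.append(days)
    hits["first_hit_day"] = pd.concat(day_cols, axis=1).min(axis=1).astype("Int64")
    return hits


def _radiology_first_days(
    df: pd.DataFrame, spec: CaseDefinitionSpec, in_window: pd.Series
) -> pd.Series:
    """First in-window imaging day with a trauma physician claim within the
    pairing window (both claims must fall inside the ascertainment window)."""
    norm = df["code"].map(normalize_code)
    rad = df.loc[
        (df["source"] == "radiology_billing")
        & in_window
        & norm.isin(spec.radiology_billing_codes),
        ["patient_id", "day"],
    ]
    trauma = df.loc[
        df["source"].isin(PHYSICIAN_SOURCES)
        & in_window
        & (df["code_system"] == "ICD9")
        & norm.str.startswith(spec.trauma_code_prefixes),
        ["patient_id", "day"],
    ]
    if rad.empty or trauma.empty:
        return pd.Series(dtype=float)
    pairs = rad.merge(trauma, on="patient_id", suffixes=("_rad", "_trauma"))
    ok = (pairs["day_rad"] - pairs["day_trauma"]).abs() <= spec.pairing_window_days
    return pairs.loc[ok].groupby("patient_id")["day_rad"].min()


def build_response_patterns(hits: pd.DataFrame) -> ResponsePatternCounts:
    """Collapse per-patient definition flags into 16 pattern counts."""
    if len(hits) == 0:
        raise EmptyInputError("no definition hits supplied")
    return ResponsePatternCounts.from_flags(hits[list(DEFINITIONS)].to_numpy())


def model_dimensions(n_definitions: int, n_classes: int) -> tuple[int, int, int]:
    """Pattern count, degrees of freedom, and free-parameter count of a
    latent class model with ``n_definitions`` binary tests.

    Parameters are counted as one class-prevalence (incidence) parameter
    plus one response probability per latent class per definition, i.e.
    ``1 + n_classes * n_definitions``. For two classes this is the familiar
    prevalence + (Se, Sp) per definition = ``1 + 2 J``.
    """
    if n_definitions < 1 or n_classes < 2:
        raise ArgumentError(
            f"need n_definitions >= 1 and n_classes >= 2, "
            f"got ({n_definitions}, {n_classes})"
        )
    n_patterns = 2**n_definitions
    return n_patterns, n_patterns - 1, 1 + n_classes * n_definitions


def compute_person_time(
    index_episodes: pd.DataFrame,
    hits: pd.DataFrame,
    exits: pd.DataFrame,
    window: AscertainmentWindow | None = None,
) -> tuple[pd.Series, float]:
    """Per-patient person-years at risk and their total.

    Follow-up runs from the index date to the earliest of the first
    qualifying claim, cohort exit, or ``window.max_day``; a person-year is
    365 days exactly (the window is defined in days).

    ``exits`` must carry ``patient_id, exit_date``.
    """
    window = AscertainmentWindow() if window is None else window
    df = index_episodes[["patient_id", "index_date"]].merge(
        exits[["patient_id", "exit_date"]], on="patient_id", how="left"
    )
    df = df.merge(hits[["patient_id", "first_hit_day"]], on="patient_id", how="left")
    exit_rel = (
        pd.to_datetime(df["exit_date"]) - pd.to_datetime(df["index_date"])
    ).dt.days
    if (exit_rel < 0).any():
        bad = df.loc[exit_rel < 0, "patient_id"].head(10).tolist()
        raise ValidationError(f"cohort exit precedes index date for patients {bad}")
    hit_day = df["first_hit_day"].astype(float).fillna(np.inf)
    days = np.minimum.reduce([hit_day.to_numpy(), exit_rel.to_numpy(dtype=float),
                              np.full(len(df), float(window.max_day))])
    person_years = pd.Series(days / 365.0, index=df["patient_id"].to_numpy(),
                             name="person_years")
    return person_years, float(person_years.sum())


def crude_incidence(n_cases: int, person_years: float) -> float:
    """Crude incidence rate per 100 person-years."""
    if person_years <= 0:
        raise ArgumentError(f"person_years must be positive, got {person_years}")
    return 100.0 * n_cases / person_years


def crude_median_time(hits: pd.DataFrame) -> int:
    """Median ``first_hit_day`` over patients with at least one hit.

    Even counts use the lower-median convention (the (n//2)-th order
    statistic, 0-based ``(n-1)//2``), so the result is always an observed
    day.
    """
    days = hits["first_hit_day"].dropna().to_numpy(dtype=int)
    if days.size == 0:
        raise EmptyInputError("no patient met any case definition")
    days.sort()
    return int(days[(days.size - 1) // 2])
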