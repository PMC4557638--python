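"""Death-record data model, ICD-10 cause/injury grouping, CSV I/O and covariate encoding.

A record describes one registered death from an external cause.  Causes are
grouped into three well-defined classes (non-transport accident, suicide,
homicide) plus the residual "event of undetermined intent" (EUI) class that
the rest of the package reclassifies.  "Unknown"/"unspecified" are ordinary
category levels, never missing-value markers.
"""

from __future__ import annotations

import dataclasses
import enum
import logging
import re
from typing import Iterable, Mapping, NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "CauseClass",
    "KNOWN_CAUSES",
    "EXCLUDED",
    "DeathRecord",
    "Schema",
    "EncodingMap",
    "ReadResult",
    "IcdParseError",
    "IcdDomainError",
    "InjuryMappingError",
    "ValidationError",
    "classify_cause",
    "classify_injury",
    "default_schema",
    "read_microdata",
    "read_microdata_frame",
    "write_microdata",
    "records_to_frame",
    "frame_to_records",
    "encode_covariates",
    "N_INJURY_CATEGORIES",
    "COVARIATE_FIELDS",
]


class IcdParseError(ValueError):
    """The string is not a syntactically valid ICD-10 code."""


class IcdDomainError(ValueError):
    """Valid ICD-10 code but outside the chapter this pipeline handles."""


class InjuryMappingError(KeyError):
    """An S/T code not covered by any injury-category row."""


class ValidationError(ValueError):
    """A record field takes a value outside its declared level set."""


class CauseClass(enum.Enum):
    """Cause-of-death classes; NTA/SUI/HOM carry the fixed indices 1, 2, 3."""

    NTA = 1  # non-transport accident
    SUI = 2  # suicide
    HOM = 3  # homicide
    EUI = 4  # event of undetermined intent (no matrix index)

    @property
    def index(self) -> int:
        """0-based array index for the three known causes."""
        if self is CauseClass.EUI:
            raise ValueError("EUI has no position in the 3-class index order")
        return self.value - 1


#: Fixed index order used by every downstream matrix/vector.
KNOWN_CAUSES: tuple[CauseClass, ...] = (CauseClass.NTA, CauseClass.SUI, CauseClass.HOM)

#: Sentinel returned by :func:`classify_cause` for codes dropped from analysis.
EXCLUDED = "excluded"

# letter + two digits + optional fourth character (with or without a dot)
_ICD_RE = re.compile(r"^([A-Z])([0-9]{2})(?:\.?[0-9X])?$")


def _parse_icd(code: str) -> tuple[str, int]:
    if not isinstance(code, str):
        raise IcdParseError(f"ICD code must be a string, got {type(code).__name__}")
    m = _ICD_RE.match(code.strip().upper())
    if m is None:
        raise IcdParseError(f"malformed ICD-10 code: {code!r}")
    return m.group(1), int(m.group(2))


def classify_cause(external_icd_code: str):
    """Map an external-cause ICD-10 code to a :class:`CauseClass` or ``EXCLUDED``.

    W00-X59 -> NTA, X60-X84 -> SUI, X85-Y05/Y08/Y09 -> HOM, Y10-Y34 -> EUI.
    Transport accidents (V01-V99) and neglect/maltreatment (Y06-Y07) are
    excluded from analysis.  Anything else in a valid ICD shape raises
    :class:`IcdDomainError`.
    """
    letter, num = _parse_icd(external_icd_code)
    if letter == "V":
        if 1 <= num <= 99:
            return EXCLUDED
        raise IcdDomainError(f"{external_icd_code}: V00 is not a valid external cause")
    if letter == "W":
        return CauseClass.NTA
    if letter == "X":
        if num <= 59:
            return CauseClass.NTA
        if num <= 84:
            return CauseClass.SUI
        return CauseClass.HOM
    if letter == "Y":
        if num <= 5:
            return CauseClass.HOM
        if num <= 7:
            return EXCLUDED
        if num <= 9:
            return CauseClass.HOM
        if num <= 34:
            return CauseClass.EUI
        raise IcdDomainError(
            f"{external_icd_code}: outside the external-cause range handled (V01-Y34)"
        )
    raise IcdDomainError(f"{external_icd_code}: not an external-cause chapter code")


N_INJURY_CATEGORIES = 19

# Category rows in priority order: specific single-code rows are inserted
# first so broader ranges (S20-S29, T36-T65) cannot shadow them.
_INJURY_ROWS: list[tuple[int, str, Sequence[int]]] = [
    (1, "S", [2]),
    (2, "S", [6]),
    (3, "S", [0, 1, 3, 4, 5, 7, 8, 9]),
    (4, "S", range(10, 20)),
    (5, "S", [21]),
    (6, "S", range(20, 30)),
    (7, "S", range(30, 40)),
    (8, "S", range(40, 100)),
    (9, "T", range(15, 20)),
    (10, "T", range(20, 33)),
    (11, "T", range(33, 36)),
    (12, "T", [40]),
    (13, "T", [51]),
    (14, "T", [58]),
    (15, "T", range(36, 66)),
    (16, "T", [68, 69]),
    (17, "T", [71]),
    (18, "T", [75]),
    (19, "T", list(range(0, 15)) + [66, 67, 70, 72, 73, 74] + list(range(76, 99))),
]

_INJURY_LOOKUP: dict[tuple[str, int], int] = {}
for _cat, _letter, _nums in _INJURY_ROWS:
    for _n in _nums:
        _INJURY_LOOKUP.setdefault((_letter, _n), _cat)


def classify_injury(nature_of_injury_icd_code: str) -> int:
    """Map a nature-of-injury ICD-10 S/T code to its category 1-19."""
    letter, num = _parse_icd(nature_of_injury_icd_code)
    if letter not in ("S", "T"):
        raise IcdDomainError(
            f"{nature_of_injury_icd_code}: nature-of-injury codes are S00-T98"
        )
    try:
        return _INJURY_LOOKUP[(letter, num)]
    except KeyError:
        raise InjuryMappingError(
            f"{nature_of_injury_icd_code}: not covered by any injury-category row"
        ) from None


# ---------------------------------------------------------------------------
# Schema and record model
# ---------------------------------------------------------------------------

#: The ten covariates, in the fixed encoding order.
COVARIATE_FIELDS: tuple[str, ...] = (
    "identity_known",
    "age_group",
    "year",
    "day_type",
    "season",
    "region",
    "urban_rural",
    "injury_category",
    "alcohol",
    "place",
)

AGE_GROUPS = ("0-14", "15-24", "25-34", "35-44", "45-54", "55-64", "65+", "unknown")
KNOWN_AGE_GROUPS = AGE_GROUPS[:-1]
DAY_TYPES = ("post_holiday_or_monday", "other")
SEASONS = ("winter", "summer", "spring_autumn")
URBAN_RURAL = ("urban", "rural")
YES_NO = ("yes", "no")
PLACES = (
    "home",
    "residential_institution",
    "school_public_admin",
    "sports",
    "street_highway",
    "trade_service",
    "other_specified",
    "unspecified",
)
SEXES = ("male", "female")


@dataclasses.dataclass(frozen=True)
class Schema:
    """Declared level sets, one entry per covariate, all values as strings."""

    levels: Mapping[str, tuple[str, ...]]

    def __post_init__(self) -> None:
        missing = set(COVARIATE_FIELDS) - set(self.levels)
        if missing:
            raise ValidationError(f"schema missing covariates: {sorted(missing)}")
        for field, lv in self.levels.items():
            if len(set(lv)) != len(lv):
                raise ValidationError(f"duplicate levels for {field}")

    def validate_value(self, field: str, value: str) -> None:
        if value not in self.levels[field]:
            raise ValidationError(
                f"value {value!r} not in declared levels of {field}: "
                f"{self.levels[field]}"
            )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, n_regions: int = 9) -> "Schema":
        """Default schema whose year levels are taken from the data."""
        years = tuple(sorted(frame["year"].astype(str).unique()))
        return default_schema(years=years, n_regions=n_regions)


def default_schema(
    years: Sequence = (2009, 2010, 2011), n_regions: int = 9
) -> Schema:
    """The bundled schema: paper-style level sets, configurable years/regions."""
    return Schema(
        levels={
            "identity_known": YES_NO,
            "age_group": AGE_GROUPS,
            "year": tuple(str(y) for y in years),
            "day_type": DAY_TYPES,
            "season": SEASONS,
            "region": tuple(f"r{i}" for i in range(1, n_regions + 1)),
            "urban_rural": URBAN_RURAL,
            "injury_category": tuple(str(c) for c in range(1, 20)),
            "alcohol": YES_NO,
            "place": PLACES,
        }
    )


@dataclasses.dataclass
class DeathRecord:
    """One registered death from an external cause."""

    sex: str
    age_group: str
    year: str
    day_type: str
    season: str
    region: str
    urban_rural: str
    injury_category: str
    alcohol: str
    place: str
    identity_known: str
    cause_class: CauseClass
    record_id: Optional[str] = None
    icd_external: Optional[str] = None
    icd_injury: Optional[str] = None
    # Carried through I/O for audit but never used as covariates.
    certifier: Optional[str] = None
    death_location: Optional[str] = None

    def validate(self, schema: Schema) -> None:
        if self.sex not in SEXES:
            raise ValidationError(f"sex {self.sex!r} not in {SEXES}")
        for field in COVARIATE_FIELDS:
            schema.validate_value(field, getattr(self, field))
        if self.icd_external:
            derived = classify_cause(self.icd_external)
            if derived != self.cause_class:
                raise ValidationError(
                    f"cause_class {self.cause_class} inconsistent with "
                    f"external code {self.icd_external} ({derived})"
                )


_CSV_COLUMNS = (
    "record_id",
    "sex",
    "age_group",
    "year",
    "day_type",
    "season",
    "region",
    "urban_rural",
    "injury_category",
    "alcohol",
    "place",
    "identity_known",
    "cause_class",
    "icd_external",
    "icd_injury",
    "certifier",
    "death_location",
)


class ReadResult(NamedTuple):
    records: list
    n_excluded: int


def read_microdata_frame(path, schema: Optional[Schema] = None):
    """Read a microdata CSV into a validated DataFrame.

    Rows whose external-cause code falls outside the analysis scope
    (transport accidents, neglect/maltreatment) are dropped and counted.
    Returns ``(frame, n_excluded)``.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = set(COVARIATE_FIELDS) | {"sex"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"microdata CSV missing columns: {sorted(missing)}")
    for col in _CSV_COLUMNS:
        if col not in df.columns:
            df[col] = ""
    n_excluded = 0
    if (df["icd_external"] != "").any():
        derived = []
        keep = np.ones(len(df), dtype=bool)
        for pos, code in enumerate(df["icd_external"].tolist()):
            if not code:
                derived.append("")
                continue
            cause = classify_cause(code)
            if cause is EXCLUDED or cause == EXCLUDED:
                keep[pos] = False
                derived.append("")
                continue
            derived.append(cause.name)
        df = df.assign(_derived=derived)
        n_excluded = int((~keep).sum())
        df = df.loc[keep].reset_index(drop=True)
        blank = df["cause_class"] == ""
        mismatch = (~blank) & (df["_derived"] != "") & (
            df["cause_class"] != df["_derived"]
        )
        if mismatch.any():
            row = int(np.flatnonzero(mismatch.to_numpy())[0])
            raise ValidationError(
                f"row {row}: cause_class {df['cause_class'].iloc[row]!r} "
                f"inconsistent with icd_external {df['icd_external'].iloc[row]!r}"
            )
        df.loc[blank, "cause_class"] = df.loc[blank, "_derived"]
        df = df.drop(columns="_derived")
    if n_excluded:
        logger.info("excluded %d out-of-scope records", n_excluded)

    if schema is None:
        schema = Schema.from_frame(df)
    valid_causes = {c.name for c in CauseClass}
    for pos, value in enumerate(df["cause_class"].tolist()):
        if value not in valid_causes:
            raise ValidationError(f"row {pos}: unknown cause_class {value!r}")
    for field in ("sex",) + COVARIATE_FIELDS:
        levels = SEXES if field == "sex" else schema.levels[field]
        bad = ~df[field].isin(levels)
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValidationError(
                f"row {row}: value {df[field].iloc[row]!r} not a declared "
                f"level of {field}"
            )
    return df, n_excluded


def read_microdata(path, schema: Optional[Schema] = None) -> ReadResult:
    """Read a microdata CSV into :class:`DeathRecord` objects."""
    df, n_excluded = read_microdata_frame(path, schema)
    return ReadResult(frame_to_records(df), n_excluded)


def records_to_frame(records: Iterable[DeathRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        d = dataclasses.asdict(r)
        d["cause_class"] = r.cause_class.name
        rows.append(d)
    df = pd.DataFrame(rows)
    return df.reindex(columns=list(_CSV_COLUMNS)).fillna("")


def frame_to_records(frame: pd.DataFrame) -> list:
    records = []
    for row in frame.itertuples(index=False):
        records.append(
            DeathRecord(
                sex=row.sex,
                age_group=row.age_group,
                year=str(row.year),
                day_type=row.day_type,
                season=row.season,
                region=row.region,
                urban_rural=row.urban_rural,
                injury_category=str(row.injury_category),
                alcohol=row.alcohol,
                place=row.place,
                identity_known=row.identity_known,
                cause_class=CauseClass[row.cause_class],
                record_id=getattr(row, "record_id", "") or None,
                icd_external=getattr(row, "icd_external", "") or None,
                icd_injury=getattr(row, "icd_injury", "") or None,
                certifier=getattr(row, "certifier", "") or None,
                death_location=getattr(row, "death_location", "") or None,
            )
        )
    return records


def write_microdata(records_or_frame, path) -> None:
    """Write records to canonical CSV (comma-separated, UTF-8, header)."""
    if isinstance(records_or_frame, pd.DataFrame):
        df = records_or_frame.reindex(columns=list(_CSV_COLUMNS)).fillna("")
    else:
        df = records_to_frame(records_or_frame)
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Covariate encoding
# ---------------------------------------------------------------------------


class EncodingError(ValueError):
    pass


@dataclasses.dataclass
class EncodingMap:
    """Dummy/one-hot expansion of the ten covariates with reference levels.

    Column 0 is the intercept; each remaining column is one non-reference
    level of one covariate, named ``field=level``, in the fixed covariate
    order.  Vector length is therefore ``1 + sum(len(levels) - 1)``.
    """

    fields: tuple[str, ...]
    levels: dict
    reference: dict

    def __post_init__(self) -> None:
        self.columns: tuple[str, ...] = ("intercept",) + tuple(
            f"{f}={lv}"
            for f in self.fields
            for lv in self.levels[f]
            if lv != self.reference[f]
        )
        # (field, level) -> column position; reference levels map to -1.
        self._index: dict[tuple[str, str], int] = {}
        pos = 1
        for f in self.fields:
            for lv in self.levels[f]:
                if lv == self.reference[f]:
                    self._index[(f, lv)] = -1
                else:
                    self._index[(f, lv)] = pos
                    pos += 1

    @property
    def n_columns(self) -> int:
        return len(self.columns)

    @classmethod
    def from_schema(
        cls,
        schema: Schema,
        training: Optional[pd.DataFrame] = None,
        reference: Optional[Mapping[str, str]] = None,
    ) -> "EncodingMap":
        """Build an encoding; reference level per covariate defaults to the
        most frequent level in ``training`` (first declared level otherwise)."""
        ref = {}
        for f in COVARIATE_FIELDS:
            if reference is not None and f in reference:
                ref[f] = reference[f]
            elif training is not None:
                counts = training[f].astype(str).value_counts()
                if len(counts) == 0:
                    ref[f] = schema.levels[f][0]
                else:
                    top = counts.max()
                    # deterministic tie-break: declared level order
                    ref[f] = next(
                        lv for lv in schema.levels[f] if counts.get(lv, 0) == top
                    )
            else:
                ref[f] = schema.levels[f][0]
            if ref[f] not in schema.levels[f]:
                raise EncodingError(
                    f"reference level {ref[f]!r} not declared for {f}"
                )
        return cls(
            fields=COVARIATE_FIELDS,
            levels={f: tuple(schema.levels[f]) for f in COVARIATE_FIELDS},
            reference=ref,
        )

    def encode_record(self, record: DeathRecord) -> np.ndarray:
        x = np.zeros(self.n_columns)
        x[0] = 1.0
        for f in self.fields:
            value = str(getattr(record, f))
            try:
                pos = self._index[(f, value)]
            except KeyError:
                raise EncodingError(
                    f"level {value!r} of {f} absent from encoding map"
                ) from None
            if pos >= 0:
                x[pos] = 1.0
        return x

    def encode_frame(self, frame: pd.DataFrame) -> np.ndarray:
        n = len(frame)
        X = np.zeros((n, self.n_columns))
        X[:, 0] = 1.0
        rows = np.arange(n)
        for f in self.fields:
            mapping = {lv: self._index[(f, lv)] for lv in self.levels[f]}
            pos = frame[f].astype(str).map(mapping)
            if pos.isna().any():
                bad = frame[f][pos.isna()].iloc[0]
                raise EncodingError(f"level {bad!r} of {f} absent from encoding map")
            pos = pos.to_numpy(dtype=np.int64)
            hit = pos >= 0
            X[rows[hit], pos[hit]] = 1.0
        return X

    def to_dict(self) -> dict:
        return {
            "fields": list(self.fields),
            "levels": {f: list(self.levels[f]) for f in self.fields},
            "reference": dict(self.reference),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "EncodingMap":
        return cls(
            fields=tuple(d["fields"]),
            levels={f: tuple(lv) for f, lv in d["levels"].items()},
            reference=dict(d["reference"]),
        )


def encode_covariates(record: DeathRecord, encoding: EncodingMap) -> np.ndarray:
    """Indicator vector for one record under the given encoding map."""
    return encoding.encode_record(record)
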