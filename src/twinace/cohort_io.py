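"""Cohort table I/O, zygosity exclusion rules, and twin-pair assembly.

The cohort format is a CSV with one row per individual (see
``synthetic_data.BASE_COLUMNS`` for the canonical column dictionary).
Arbitrary headers are mapped onto canonical names via a schema-config
mapping.  Blank cells mean "missing"; categorical values are validated
case-insensitively against their enumerations.

Exclusions follow the twin-design entry criteria: a family is removed if
any member's zygosity is missing, if its members carry discordant
zygosity labels, or if it does not contain exactly two member rows.  The
rules are applied in that order so each family is counted under exactly
one rule.
"""

from __future__ import annotations

import dataclasses
from collections import OrderedDict
from dataclasses import dataclass, field

import pandas as pd

from .synthetic_data import BASE_COLUMNS, RACES, SEXES

ZYGOSITIES = ("MZ", "DZ")
_YESNO = ("yes", "no")

CURIOUS_LEVELS = (
    "Not at all curious",
    "A little curious",
    "Somewhat curious",
    "Very curious",
)
WILLING_LEVELS = (
    "Definitely not",
    "Probably not",
    "Probably yes",
    "Definitely yes",
)

#: optional covariate columns accepted (and passed through) when present
OPTIONAL_COLUMNS = [
    "parent_education",
    "family_income",
    "family_difficulty",
    "premature",
    "neigh_safety_child",
    "neigh_safety_parent",
]


class SchemaError(ValueError):
    """The file's headers cannot be mapped onto the cohort schema."""


class PairingError(ValueError):
    """A family violates the same-sex two-member pair contract."""


@dataclass
class IndividualRecord:
    """One child's raw fields, blanks kept as empty strings."""

    family_id: str
    member_index: int
    zygosity: str  # "MZ" | "DZ" | ""
    sex: str
    race_eth: str
    age_months: float | None
    heard_alcohol: str = ""
    sipped: str = ""
    curious: str = ""
    try_soon: str = ""
    friend_offer: str = ""
    extra: dict = field(default_factory=dict)


@dataclass
class TwinPair:
    """A validated same-family duo, members ordered by member_index."""

    family_id: str
    zygosity: str
    members: tuple[IndividualRecord, IndividualRecord]
    traits: dict = field(default_factory=dict)


@dataclass
class RowError:
    row: int
    column: str
    value: str
    message: str


@dataclass
class ExclusionReport:
    entry_pairs: int
    excluded_missing_zygosity: int
    excluded_inconsistent_zygosity: int
    excluded_not_two_members: int
    retained_pairs: int

    @property
    def entry_individuals(self) -> int:
        return 2 * self.entry_pairs

    @property
    def retained_individuals(self) -> int:
        return 2 * self.retained_pairs

    def to_frame(self) -> pd.DataFrame:
        d = dataclasses.asdict(self)
        return pd.DataFrame({"category": list(d), "pairs": list(d.values())})


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------

_ENUMS = {
    "zygosity": ZYGOSITIES,
    "sex": SEXES,
    "race_eth": RACES,
    "heard_alcohol": _YESNO,
    "sipped": _YESNO,
    "curious": CURIOUS_LEVELS,
    "try_soon": WILLING_LEVELS,
    "friend_offer": WILLING_LEVELS,
}


def _canon(value: str, column: str) -> tuple[str, str | None]:
    """Map *value* onto the column's enumeration, case-insensitively.
    Returns (canonical_value, error_message_or_None)."""
    if value == "":
        return "", None
    allowed = _ENUMS[column]
    for a in allowed:
        if value.strip().lower() == a.lower():
            return a, None
    return value, f"{value!r} not in {allowed} for column {column}"


def read_cohort(
    path, schema_config: dict[str, str] | None = None
) -> tuple[list[IndividualRecord], list[RowError]]:
    """Read a cohort CSV into records, collecting row-level validation
    errors instead of silently coercing out-of-enumeration values.

    ``schema_config`` maps file headers to canonical column names; columns
    already canonically named need no entry.
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    if schema_config:
        raw = raw.rename(columns=schema_config)
    missing = [c for c in ("family_id", "member_index", "zygosity") if c not in raw.columns]
    if missing:
        raise SchemaError(
            f"required columns {missing} absent after schema mapping; "
            f"got {list(raw.columns)}"
        )
    records: list[IndividualRecord] = []
    errors: list[RowError] = []
    for i, row in enumerate(raw.itertuples(index=False)):
        vals = dict(zip(raw.columns, row))
        fields = {}
        for col in _ENUMS:
            v, err = _canon(vals.get(col, ""), col)
            fields[col] = v
            if err:
                errors.append(RowError(i, col, vals.get(col, ""), err))
        fam = vals.get("family_id", "").strip()
        if fam == "":
            errors.append(RowError(i, "family_id", "", "family_id is empty"))
        try:
            idx = int(float(vals.get("member_index", "") or 0))
        except ValueError:
            errors.append(RowError(i, "member_index", vals["member_index"],
                                   "member_index not an integer"))
            idx = 0
        age_raw = vals.get("age_months", "")
        age = float(age_raw) if age_raw != "" else None
        extra = {c: vals[c] for c in raw.columns
                 if c not in BASE_COLUMNS and c in vals}
        records.append(IndividualRecord(
            family_id=fam, member_index=idx, age_months=age,
            extra=extra, **fields))
    return records, errors


def records_to_frame(records: list[IndividualRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        d = {c: getattr(r, c) for c in BASE_COLUMNS}
        d.update(r.extra)
        rows.append(d)
    return pd.DataFrame(rows)


def frame_to_records(frame: pd.DataFrame) -> list[IndividualRecord]:
    records = []
    for _, row in frame.iterrows():
        extra = {c: row[c] for c in frame.columns if c not in BASE_COLUMNS}
        records.append(IndividualRecord(
            family_id=str(row["family_id"]),
            member_index=int(row["member_index"]),
            zygosity=str(row.get("zygosity", "") or ""),
            sex=str(row.get("sex", "") or ""),
            race_eth=str(row.get("race_eth", "") or ""),
            age_months=(None if pd.isna(row.get("age_months")) else float(row["age_months"])),
            heard_alcohol=str(row.get("heard_alcohol", "") or ""),
            sipped=str(row.get("sipped", "") or ""),
            curious=str(row.get("curious", "") or ""),
            try_soon=str(row.get("try_soon", "") or ""),
            friend_offer=str(row.get("friend_offer", "") or ""),
            extra=extra,
        ))
    return records


def write_cohort(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Exclusions and pairing
# ---------------------------------------------------------------------------

def _group_by_family(records: list[IndividualRecord]) -> "OrderedDict[str, list[IndividualRecord]]":
    fams: OrderedDict[str, list[IndividualRecord]] = OrderedDict()
    for r in records:
        fams.setdefault(r.family_id, []).append(r)
    return fams


def apply_exclusions(
    records: list[IndividualRecord],
) -> tuple[list[IndividualRecord], ExclusionReport]:
    """Remove families failing the zygosity entry criteria.

    Order of precedence: missing zygosity, then inconsistent zygosity,
    then families without exactly two member rows.  Defective input is
    the expected case; no exception is raised.
    """
    fams = _group_by_family(records)
    n_missing = n_incons = n_size = 0
    retained: list[IndividualRecord] = []
    for members in fams.values():
        zygs = [m.zygosity for m in members]
        if any(z == "" for z in zygs):
            n_missing += 1
        elif len(set(zygs)) > 1:
            n_incons += 1
        elif len(members) != 2:
            n_size += 1
        else:
            retained.extend(members)
    report = ExclusionReport(
        entry_pairs=len(fams),
        excluded_missing_zygosity=n_missing,
        excluded_inconsistent_zygosity=n_incons,
        excluded_not_two_members=n_size,
        retained_pairs=len(fams) - n_missing - n_incons - n_size,
    )
    return retained, report


def pair_twins(records: list[IndividualRecord]) -> list[TwinPair]:
    """Assemble one TwinPair per family, members in member_index order.

    Must run after :func:`apply_exclusions`.  A sex-discordant family is
    an error: the design enrolls same-sex pairs only.
    """
    pairs = []
    for fam, members in _group_by_family(records).items():
        if len(members) != 2:
            raise PairingError(
                f"family {fam}: expected 2 members, got {len(members)}; "
                "run apply_exclusions first")
        m = sorted(members, key=lambda r: r.member_index)
        if m[0].sex != m[1].sex:
            raise PairingError(f"family {fam}: members have discordant sex "
                               f"({m[0].sex!r} vs {m[1].sex!r})")
        pairs.append(TwinPair(family_id=fam, zygosity=m[0].zygosity,
                              members=(m[0], m[1])))
    return pairs
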