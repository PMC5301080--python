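"""ATC code handling and the DDD drug registry.

The WHO Anatomical Therapeutic Chemical (ATC) system codes drugs
hierarchically: one letter (anatomical main group), two digits
(therapeutic subgroup), two letters (pharmacological / chemical
subgroups), two digits (chemical substance) — e.g. ``N05AH02`` is
clozapine, living under ``N05A`` (antipsychotics).  The defined daily
dose (DDD) is the WHO's assumed average maintenance dose per day for a
drug's main indication; it is presentation-specific (oral risperidone
and its long-acting injectable carry different DDDs), so the registry
keys entries by ``(atc, route, form)``.

Lithium shares the ``N05A`` therapeutic subgroup with the
antipsychotics but is not one; antipsychotic membership therefore
excludes the ``N05AN`` chemical subgroup.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from typing import Iterable, Iterator

import pandas as pd

__all__ = [
    "AtcCode",
    "AtcError",
    "DrugEntry",
    "DrugRegistry",
    "Form",
    "Route",
    "UnknownDrugError",
    "default_registry",
    "is_antipsychotic",
    "parse_atc",
]

#: Valid ATC prefix lengths (anatomical .. chemical-substance level).
_VALID_LENGTHS = (1, 3, 4, 5, 7)

# Character-class predicate per position of a full 7-character code.
_POSITION_CLASSES = (
    ("letter", str.isalpha),
    ("digit", str.isdigit),
    ("digit", str.isdigit),
    ("letter", str.isalpha),
    ("letter", str.isalpha),
    ("digit", str.isdigit),
    ("digit", str.isdigit),
)

ANTIPSYCHOTIC_GROUP = "N05A"
LITHIUM_SUBGROUP = "N05AN"


class AtcError(ValueError):
    """Raised for malformed ATC codes or insufficiently specific queries."""


class UnknownDrugError(KeyError):
    """Raised when a registry lookup finds no matching entry."""


@dataclass(frozen=True, order=True)
class AtcCode:
    """A validated ATC code or code prefix.

    Construct via :func:`parse_atc`, which validates the grammar and
    normalizes case.
    """

    code: str

    def __str__(self) -> str:  # render; parse_atc(str(c)) round-trips
        return self.code

    def __len__(self) -> int:
        return len(self.code)

    def level(self, n_chars: int) -> str:
        """Prefix of ``n_chars`` characters (1, 3, 4, 5 or 7).

        ``AtcCode("N05AL05").level(5)`` is ``"N05AL"``; ``.level(3)``
        is ``"N05"``.
        """
        if n_chars not in _VALID_LENGTHS:
            raise AtcError(f"no ATC level has {n_chars} characters; valid: {_VALID_LENGTHS}")
        if n_chars > len(self.code):
            raise AtcError(f"code {self.code!r} is shorter than {n_chars} characters")
        return self.code[:n_chars]

    def startswith(self, prefix: str) -> bool:
        return self.code.startswith(prefix.upper())


def parse_atc(text: str) -> AtcCode:
    """Validate and normalize an ATC code or prefix.

    Accepts full 7-character codes and group prefixes of length 1, 3,
    4 or 5; lowercase input is upcased.  Raises :class:`AtcError`
    naming the first offending position on grammar violations.
    """
    if not text:
        raise AtcError("empty ATC code")
    code = text.strip().upper()
    if len(code) not in _VALID_LENGTHS:
        raise AtcError(
            f"ATC code {code!r} has length {len(code)}; valid lengths are {_VALID_LENGTHS}"
        )
    for pos, (cls_name, pred) in enumerate(_POSITION_CLASSES[: len(code)]):
        ch = code[pos]
        if not (pred(ch) and ch.isascii()):
            raise AtcError(
                f"ATC code {code!r}: position {pos + 1} must be a {cls_name}, got {ch!r}"
            )
    return AtcCode(code)


def is_antipsychotic(code: AtcCode | str) -> bool:
    """True iff ``code`` falls under N05A excluding lithium (N05AN).

    Requires at least the chemical-group level (4 characters); shorter
    prefixes cannot decide membership and raise :class:`AtcError`.
    """
    if isinstance(code, str):
        code = parse_atc(code)
    if len(code) < 4:
        raise AtcError(
            f"code {code.code!r} is too short to decide antipsychotic membership "
            "(need at least 4 characters)"
        )
    return code.startswith(ANTIPSYCHOTIC_GROUP) and not code.startswith(LITHIUM_SUBGROUP)


class Route(str, Enum):
    ORAL = "oral"
    INJECTABLE = "injectable"


class Form(str, Enum):
    STANDARD = "standard"
    LONG_ACTING = "long_acting"


@dataclass(frozen=True)
class DrugEntry:
    """One registry row: a drug presentation with its DDD in mg/day."""

    atc: AtcCode
    name: str
    route: Route
    form: Form
    ddd_mg_per_day: float

    def __post_init__(self) -> None:
        if not self.ddd_mg_per_day > 0:
            raise ValueError(f"DDD must be positive, got {self.ddd_mg_per_day}")

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.atc.code, self.route.value, self.form.value)

    @property
    def is_antipsychotic(self) -> bool:
        return is_antipsychotic(self.atc)


def _normalize_name(name: str) -> str:
    return re.sub(r"\s+", " ", name.strip().lower())


class DrugRegistry:
    """DDD registry indexed by ``(atc, route, form)`` and by name."""

    def __init__(self, entries: Iterable[DrugEntry] = ()) -> None:
        self._by_key: dict[tuple[str, str, str], DrugEntry] = {}
        self._by_name: dict[str, DrugEntry] = {}
        for e in entries:
            self.add(e)

    def add(self, entry: DrugEntry) -> None:
        if entry.key in self._by_key:
            raise ValueError(f"duplicate registry entry for {entry.key}")
        self._by_key[entry.key] = entry
        self._by_name[_normalize_name(entry.name)] = entry

    def __len__(self) -> int:
        return len(self._by_key)

    def __iter__(self) -> Iterator[DrugEntry]:
        return iter(self._by_key.values())

    def lookup(
        self,
        atc: AtcCode | str,
        route: Route | str = Route.ORAL,
        form: Form | str = Form.STANDARD,
    ) -> DrugEntry:
        atc = parse_atc(atc) if isinstance(atc, str) else atc
        key = (atc.code, Route(route).value, Form(form).value)
        try:
            return self._by_key[key]
        except KeyError:
            near = sorted(
                e.name for e in self if e.atc.level(min(5, len(atc))) == atc.level(min(5, len(atc)))
            )
            hint = f"; nearest by ATC prefix: {', '.join(near)}" if near else ""
            raise UnknownDrugError(f"no registry entry for {key}{hint}") from None

    def lookup_by_name(self, name: str) -> DrugEntry:
        try:
            return self._by_name[_normalize_name(name)]
        except KeyError:
            raise UnknownDrugError(f"no registry entry named {name!r}") from None

    def lookup_ddd(
        self,
        atc: AtcCode | str,
        route: Route | str = Route.ORAL,
        form: Form | str = Form.STANDARD,
    ) -> float:
        """DDD (mg/day) for one drug presentation."""
        return self.lookup(atc, route, form).ddd_mg_per_day

    def antipsychotics(self) -> list[DrugEntry]:
        return [e for e in self if e.is_antipsychotic]

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "DrugRegistry":
        required = {"atc", "name", "route", "form", "ddd_mg"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"registry table missing columns: {sorted(missing)}")
        entries = (
            DrugEntry(
                atc=parse_atc(str(row.atc)),
                name=str(row.name_),
                route=Route(str(row.route)),
                form=Form(str(row.form)),
                ddd_mg_per_day=float(row.ddd_mg),
            )
            for row in df.rename(columns={"name": "name_"}).itertuples(index=False)
        )
        return cls(entries)

    @classmethod
    def from_csv(cls, path) -> "DrugRegistry":
        # sep=None autodetects comma vs tab
        df = pd.read_csv(path, sep=None, engine="python", encoding="utf-8")
        return cls.from_frame(df)


def default_registry() -> DrugRegistry:
    """The shipped antipsychotic registry (18 presentations, 19 entries).

    Mirrors the utilization reference table bundled with the package;
    tiapride, marketed both orally and as an injectable with the same
    DDD, appears once per route.
    """
    with resources.files("psyrx.data").joinpath("registry.csv").open("rb") as fh:
        return DrugRegistry.from_csv(fh)
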