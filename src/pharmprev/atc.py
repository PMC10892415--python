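"""ATC code handling and Defined Daily Dose (DDD) lookup.

The Anatomical Therapeutic Chemical (ATC) classification arranges drugs in a
five-level hierarchy encoded positionally in the code string:

=====  ======  =======================  ==============
level  length  meaning                  example
=====  ======  =======================  ==============
1      1       anatomical main group    ``A``
2      3       therapeutic subgroup     ``A10``
3      4       pharmacological subgroup ``A10B``
4      5       chemical subgroup        ``A10BA``
5      7       active substance         ``A10BA02``
=====  ======  =======================  ==============

For diabetes pharmacotherapy the two level-3 classes of interest are
``A10A`` (insulins and analogues) and ``A10B`` (blood-glucose-lowering
drugs excluding insulins, "NADs").

A :class:`DDDRegistry` maps level-5 codes to their Defined Daily Dose — the
assumed average maintenance dose per day for the drug's main adult
indication — which normalises heterogeneous dispensing volumes into
comparable patient-day equivalents.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping

__all__ = [
    "ATCFormatError",
    "MissingDDDError",
    "DDDEntry",
    "DDDRegistry",
    "atc_level",
    "code_level",
    "classify_ad",
    "validate_atc",
]

#: string length of an ATC code at each hierarchy level
LEVEL_LENGTHS: Mapping[int, int] = {1: 1, 2: 3, 3: 4, 4: 5, 5: 7}

_LENGTH_TO_LEVEL = {v: k for k, v in LEVEL_LENGTHS.items()}

# Positional grammar of a full level-5 code: letter, 2 digits, 2 letters,
# 2 digits.  Prefixes follow the same template truncated at a level break.
_PATTERNS = {
    1: re.compile(r"^[A-Z]$"),
    3: re.compile(r"^[A-Z]\d\d$"),
    4: re.compile(r"^[A-Z]\d\d[A-Z]$"),
    5: re.compile(r"^[A-Z]\d\d[A-Z][A-Z]$"),
    7: re.compile(r"^[A-Z]\d\d[A-Z][A-Z]\d\d$"),
}

#: admissible DDD units: milligrams, international units, and unit doses
#: (the latter reserved for fixed-dose combination products)
DDD_UNITS = frozenset({"mg", "IU", "UD"})


class ATCFormatError(ValueError):
    """Raised when a string is not a structurally valid ATC code."""


class MissingDDDError(KeyError):
    """Raised when a registry has no DDD entry for a requested code."""

    def __init__(self, code: str):
        super().__init__(code)
        self.code = code

    def __str__(self) -> str:  # KeyError quotes its arg; keep a sentence
        return f"no DDD entry for ATC code {self.code!r}"


def validate_atc(code: str) -> str:
    """Normalise and validate an ATC code, returning its canonical form.

    Leading/trailing whitespace is stripped and the code upper-cased; any
    other deviation from the positional grammar raises
    :class:`ATCFormatError`.
    """
    if not isinstance(code, str):
        raise ATCFormatError(f"ATC code must be a string, got {type(code).__name__}")
    canon = code.strip().upper()
    pattern = _PATTERNS.get(len(canon))
    if pattern is None or not pattern.match(canon):
        raise ATCFormatError(f"invalid ATC code {code!r}")
    return canon


def code_level(code: str) -> int:
    """Return the hierarchy level (1–5) encoded by the code's length."""
    canon = validate_atc(code)
    return _LENGTH_TO_LEVEL[len(canon)]


def atc_level(code: str, level: int) -> str:
    """Truncate ``code`` to its ancestor at ``level``.

    The requested level must not be deeper than the code's own level.
    Idempotent: ``atc_level(atc_level(c, k), k) == atc_level(c, k)``.
    """
    canon = validate_atc(code)
    if level not in LEVEL_LENGTHS:
        raise ValueError(f"ATC level must be 1-5, got {level}")
    length = LEVEL_LENGTHS[level]
    if length > len(canon):
        raise ValueError(
            f"code {canon!r} is level {_LENGTH_TO_LEVEL[len(canon)]}, "
            f"cannot extract level {level}"
        )
    return canon[:length]


def classify_ad(code: str) -> str:
    """Classify a code as ``'insulin'`` (A10A), ``'nad'`` (A10B) or ``'other'``.

    NAD = non-insulin antidiabetic drug.  Codes above level 3 (e.g. ``A10``
    itself) cannot be split between the two classes and map to ``'other'``.
    """
    canon = validate_atc(code)
    if canon.startswith("A10A"):
        return "insulin"
    if canon.startswith("A10B"):
        return "nad"
    return "other"


@dataclass(frozen=True)
class DDDEntry:
    """One DDD assignment: level-5 ATC code, quantity, unit, route."""

    atc: str
    ddd_quantity: float
    ddd_unit: str
    route: str = "oral"

    def __post_init__(self) -> None:
        object.__setattr__(self, "atc", validate_atc(self.atc))
        if code_level(self.atc) != 5:
            raise ATCFormatError(f"DDD entries require a level-5 code, got {self.atc!r}")
        if not self.ddd_quantity > 0:
            raise ValueError(f"ddd_quantity must be positive, got {self.ddd_quantity}")
        if self.ddd_unit not in DDD_UNITS:
            raise ValueError(
                f"ddd_unit must be one of {sorted(DDD_UNITS)}, got {self.ddd_unit!r}"
            )


class DDDRegistry:
    """Immutable-ish mapping from level-5 ATC code to :class:`DDDEntry`."""

    def __init__(self, entries: Iterable[DDDEntry]):
        self._entries: dict[str, DDDEntry] = {}
        for entry in entries:
            if entry.atc in self._entries:
                raise ValueError(f"duplicate DDD entry for ATC code {entry.atc!r}")
            self._entries[entry.atc] = entry

    def lookup(self, code: str) -> DDDEntry:
        """Return the entry for ``code`` or raise :class:`MissingDDDError`."""
        canon = validate_atc(code)
        try:
            return self._entries[canon]
        except KeyError:
            raise MissingDDDError(canon) from None

    def __contains__(self, code: str) -> bool:
        return validate_atc(code) in self._entries

    def __len__(self) -> int:
        return len(self._entries)

    def __iter__(self) -> Iterator[DDDEntry]:
        return iter(self._entries.values())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DDDRegistry):
            return NotImplemented
        return self._entries == other._entries

    def codes(self, atc_class: str | None = None) -> list[str]:
        """All codes, optionally restricted to a hierarchy prefix."""
        if atc_class is None:
            return sorted(self._entries)
        prefix = validate_atc(atc_class)
        return sorted(c for c in self._entries if c.startswith(prefix))

    @classmethod
    def from_csv(cls, path: str | Path) -> "DDDRegistry":
        """Load a registry from ``atc,ddd_quantity,ddd_unit,route`` CSV.

        UTF-8, comma-delimited, dot decimals; lines starting with ``#`` are
        treated as comments.
        """
        path = Path(path)
        with path.open(newline="", encoding="utf-8") as handle:
            rows = [r for r in csv.DictReader(_strip_comments(handle))]
        if not rows:
            raise ValueError(f"empty DDD registry file: {path}")
        entries = []
        for i, row in enumerate(rows, start=2):
            try:
                entries.append(
                    DDDEntry(
                        atc=row["atc"],
                        ddd_quantity=float(row["ddd_quantity"]),
                        ddd_unit=row["ddd_unit"].strip(),
                        route=(row.get("route") or "oral").strip(),
                    )
                )
            except (KeyError, TypeError, ValueError) as exc:
                raise ValueError(f"{path}, row {i}: {exc}") from exc
        return cls(entries)

    def to_csv(self, path: str | Path) -> None:
        """Write the registry in the same dialect :meth:`from_csv` reads."""
        path = Path(path)
        with path.open("w", newline="", encoding="utf-8") as handle:
            writer = csv.writer(handle)
            writer.writerow(["atc", "ddd_quantity", "ddd_unit", "route"])
            for entry in sorted(self, key=lambda e: e.atc):
                writer.writerow(
                    [entry.atc, repr(entry.ddd_quantity), entry.ddd_unit, entry.route]
                )


def _strip_comments(lines: Iterable[str]) -> Iterator[str]:
    for line in lines:
        if not line.lstrip().startswith("#"):
            yield line
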