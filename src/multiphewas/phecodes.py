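"""ICD-9-CM to phecode rollup.

Phecodes group ICD-9-CM billing codes into clinically meaningful
phenotype groups, each carrying a human-readable name and a higher-level
category (e.g. "neurological").  This module loads a mapping table,
normalizes ICD-9 codes to one canonical dialect, and performs the rollup.

ICD-9 codes circulate in two dialects: dotted ("299.00") and undotted
("29900").  The canonical form here is dotted, with the dot inserted
after the third character (fourth for E-codes); V-codes follow the
three-character rule.  Codes that the map does not cover are a normal
outcome of the rollup — they are counted and dropped, never an error.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "PhecodeMap",
    "normalize_icd9",
    "load_phecode_map",
    "Icd9Error",
    "PhecodeMapError",
]

log = logging.getLogger(__name__)

UNMAPPED = "unmapped"

_ICD9_RE = re.compile(r"^(E\d{3}|V\d{2}|\d{3})(\d{0,2})$")


class Icd9Error(ValueError):
    """Raised for a token that cannot be parsed as an ICD-9-CM code."""


class PhecodeMapError(ValueError):
    """Raised when the mapping file violates its schema or invariants."""


def normalize_icd9(raw: str) -> str:
    """Return the canonical dotted form of an ICD-9-CM code.

    Idempotent: already-canonical input is returned unchanged.

    >>> normalize_icd9("29900")
    '299.00'
    >>> normalize_icd9("V20.2")
    'V20.2'
    >>> normalize_icd9("E8120")
    'E812.0'
    """
    if not isinstance(raw, str) or not raw.strip():
        raise Icd9Error(f"empty or non-string ICD-9 token: {raw!r}")
    token = raw.strip().upper().replace(".", "")
    m = _ICD9_RE.match(token)
    if m is None:
        raise Icd9Error(f"unparseable ICD-9-CM code: {raw!r}")
    head, tail = m.groups()
    return f"{head}.{tail}" if tail else head


@dataclass
class PhecodeMap:
    """Validated ICD-9 -> phecode -> (name, category) rollup table.

    Phecode identifiers are strings throughout ("345.10" would lose its
    trailing zero as a float).
    """

    entries: pd.DataFrame = field(repr=False)
    n_dropped_missing_phecode: int = 0

    def __post_init__(self) -> None:
        required = {"icd9", "phecode", "phenotype", "category"}
        missing = required - set(self.entries.columns)
        if missing:
            raise PhecodeMapError(f"mapping table missing columns: {sorted(missing)}")
        dup = self.entries.groupby("icd9")["phecode"].nunique()
        conflicts = dup[dup > 1]
        if len(conflicts):
            raise PhecodeMapError(
                "conflicting phecode assignments for ICD-9 code(s): "
                + ", ".join(conflicts.index[:5])
            )
        per_code = self.entries.groupby("phecode")[["phenotype", "category"]].nunique()
        bad = per_code[(per_code > 1).any(axis=1)]
        if len(bad):
            raise PhecodeMapError(
                "phecode(s) with inconsistent name/category: " + ", ".join(bad.index[:5])
            )
        self._lookup = dict(zip(self.entries["icd9"], self.entries["phecode"]))
        meta = self.entries.drop_duplicates("phecode")
        self._names = dict(zip(meta["phecode"], meta["phenotype"]))
        self._categories = dict(zip(meta["phecode"], meta["category"]))

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def phecodes(self) -> set[str]:
        return set(self._names)

    def phenotype_name(self, phecode: str) -> str:
        return self._names.get(phecode, "unknown")

    def category(self, phecode: str) -> str:
        return self._categories.get(phecode, "unknown")

    def map_to_phecode(self, icd9: str) -> str:
        """Roll one ICD-9 code up to its phecode, or ``"unmapped"``."""
        return self._lookup.get(normalize_icd9(icd9), UNMAPPED)

    def map_series(self, icd9: pd.Series) -> pd.Series:
        """Vectorized rollup of an ICD-9 column (assumed pre-normalized)."""
        return icd9.map(self._lookup).fillna(UNMAPPED)


def normalize_series(icd9: pd.Series) -> pd.Series:
    """Normalize an ICD-9 column via its unique values (events repeat codes)."""
    table = {c: normalize_icd9(c) for c in icd9.unique()}
    return icd9.map(table)


def load_phecode_map(path) -> PhecodeMap:
    """Load a CSV mapping file with columns icd9, phecode, phenotype, category.

    Rows with a missing phecode are dropped with a logged count; duplicate
    (icd9, phecode) rows collapse to one entry; an icd9 mapped to two
    different phecodes is a load error.
    """
    df = pd.read_csv(path, dtype=str)
    required = {"icd9", "phecode", "phenotype", "category"}
    missing = required - set(df.columns)
    if missing:
        raise PhecodeMapError(f"mapping file {path} missing columns: {sorted(missing)}")
    n_before = len(df)
    df = df.dropna(subset=["phecode"])
    df = df[df["phecode"].str.strip() != ""]
    n_dropped = n_before - len(df)
    if n_dropped:
        log.info("phecode map: dropped %d rows with missing phecode", n_dropped)
    df = df.assign(icd9=df["icd9"].map(normalize_icd9)).drop_duplicates(
        subset=["icd9", "phecode"]
    )
    return PhecodeMap(entries=df.reset_index(drop=True), n_dropped_missing_phecode=n_dropped)
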