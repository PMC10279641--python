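"""Reading and validating tree-inventory files.

Inventories are delimited text with a header row.  Because compiled allometry
datasets arrive with heterogeneous schemas, the reader takes a
:class:`ColumnMap` translating canonical field names to source column labels
(with per-column units) rather than guessing.  Rows failing the inclusion
filters — height above breast height, crown base between breast height and the
top, at least one leaf measurement when fitting, monocots excluded — are
dropped and tallied per rule in a :class:`FilterReport`.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd
import yaml

from .geometry import BREAST_HEIGHT, TreeRecord, area_from_diameter

__all__ = ["ColumnMap", "FilterReport", "read_inventory", "write_records"]

log = logging.getLogger(__name__)

_CANONICAL = ("tree_id", "species", "pft", "leaf_habit", "leaf_form", "dbh",
              "a_bh", "height", "crown_base_height", "d_cb", "a_cb",
              "leaf_area", "leaf_mass", "monocot")

_LENGTH_UNITS = {"m": 1.0, "cm": 0.01, "mm": 0.001}
_AREA_UNITS = {"m2": 1.0, "cm2": 1e-4, "mm2": 1e-6}
_MASS_UNITS = {"kg": 1.0, "g": 1e-3}

_UNIT_KIND = {
    "dbh": _LENGTH_UNITS, "height": _LENGTH_UNITS,
    "crown_base_height": _LENGTH_UNITS, "d_cb": _LENGTH_UNITS,
    "a_bh": _AREA_UNITS, "a_cb": _AREA_UNITS, "leaf_area": _AREA_UNITS,
    "leaf_mass": _MASS_UNITS,
}


@dataclass
class ColumnMap:
    """Mapping from canonical field names to source column labels, with units.

    ``columns`` maps canonical names (``species``, ``pft`` — or the pair
    ``leaf_habit``/``leaf_form`` —, ``dbh`` or ``a_bh``, ``height``,
    ``crown_base_height``, optionally ``tree_id``, ``d_cb`` or ``a_cb``,
    ``leaf_area``, ``leaf_mass``, ``monocot``) to the labels in the file.
    ``units`` declares the unit per canonical name (m/cm/mm, m2/cm2, kg/g);
    unlisted columns are assumed to be in the canonical units (m, m², kg).
    """

    columns: Dict[str, str]
    units: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = set(self.columns) - set(_CANONICAL)
        if unknown:
            raise ValueError(f"unknown canonical field names: {sorted(unknown)}")
        for req in ("species", "height", "crown_base_height"):
            if req not in self.columns:
                raise ValueError(f"required column {req!r} is not mapped")
        if "dbh" not in self.columns and "a_bh" not in self.columns:
            raise ValueError("map at least one breast-height size column (dbh or a_bh)")
        if "pft" not in self.columns and not (
            "leaf_habit" in self.columns and "leaf_form" in self.columns
        ):
            raise ValueError(
                "map a pft column, or both leaf_habit and leaf_form to derive it"
            )
        for name, unit in self.units.items():
            kinds = _UNIT_KIND.get(name)
            if kinds is None:
                raise ValueError(f"no unit applies to column {name!r}")
            if unit not in kinds:
                raise ValueError(f"unknown unit {unit!r} for {name!r} "
                                 f"(choose from {sorted(kinds)})")

    def factor(self, name: str) -> float:
        return _UNIT_KIND.get(name, {}).get(self.units.get(name, ""), 1.0) \
            if name in self.units else 1.0

    @classmethod
    def from_yaml(cls, path) -> "ColumnMap":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls(columns=doc.get("columns", {}), units=doc.get("units", {}))


@dataclass
class FilterReport:
    """Per-rule removal counts plus retained totals overall, per PFT and per species."""

    n_input: int = 0
    removed: Dict[str, int] = field(default_factory=dict)
    retained_total: int = 0
    retained_per_pft: Dict[str, int] = field(default_factory=dict)
    retained_per_species: Dict[str, int] = field(default_factory=dict)

    @property
    def n_removed(self) -> int:
        return sum(self.removed.values())

    def check(self) -> None:
        if self.n_removed + self.retained_total != self.n_input:
            raise AssertionError("filter report does not reconcile with input count")


def _sniff_delimiter(path) -> str:
    with open(path, newline="") as fh:
        head = fh.readline()
    counts = {d: head.count(d) for d in (",", "\t", ";")}
    return max(counts, key=counts.get) if any(counts.values()) else ","


_TRUTHY = {"1", "true", "yes", "y", "t"}


def read_inventory(path, colmap: ColumnMap, delimiter: Optional[str] = None,
                   require_leaf: bool = True,
                   exclude_species: Sequence[str] = (),
                   ) -> Tuple[List[TreeRecord], FilterReport]:
    """Read an inventory file into validated, unit-normalised :class:`TreeRecord`\\ s.

    Inclusion rules (each removal is tallied under the name shown):

    * ``height_le_1.3`` — tree height must strictly exceed breast height;
    * ``crown_base_out_of_range`` — crown-base height in [1.3 m, height);
    * ``no_leaf_measurement`` — at least one of leaf area / leaf mass present
      (only when ``require_leaf`` is true; switch off for prediction-only
      inventories);
    * ``monocot_excluded`` — a truthy monocot flag, or species listed in
      ``exclude_species``;
    * ``missing_size`` — no usable breast-height diameter/area;
    * ``invalid_value`` — a mapped numeric field that is non-positive.

    Unparseable numeric text raises immediately, naming the row.
    """
    path = Path(path)
    sep = delimiter or _sniff_delimiter(path)
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=True)
    for canon, label in colmap.columns.items():
        if label not in df.columns:
            raise ValueError(f"mapped column {label!r} (for {canon!r}) "
                             f"not found in {path.name}")

    report = FilterReport(n_input=len(df))
    records: List[TreeRecord] = []
    excl = {s.strip().lower() for s in exclude_species}

    def getval(row, canon):
        label = colmap.columns.get(canon)
        if label is None:
            return None
        v = row[label]
        if pd.isna(v) or str(v).strip() == "":
            return None
        return str(v).strip()

    def getnum(row, canon, rownum):
        v = getval(row, canon)
        if v is None:
            return None
        try:
            return float(v) * colmap.factor(canon)
        except ValueError:
            raise ValueError(
                f"{path.name} row {rownum}: cannot parse {colmap.columns[canon]!r} "
                f"value {v!r} as a number"
            ) from None

    def drop(rule: str) -> None:
        report.removed[rule] = report.removed.get(rule, 0) + 1

    for i, (_, row) in enumerate(df.iterrows()):
        rownum = i + 2  # 1-based with header
        species = getval(row, "species")
        mono = getval(row, "monocot")
        if (mono is not None and mono.lower() in _TRUTHY) or \
                (species is not None and species.lower() in excl):
            drop("monocot_excluded")
            continue
        height = getnum(row, "height", rownum)
        cb = getnum(row, "crown_base_height", rownum)
        if height is None or not height > BREAST_HEIGHT:
            drop("height_le_1.3")
            continue
        if cb is None or not (BREAST_HEIGHT <= cb < height):
            drop("crown_base_out_of_range")
            continue
        a_bh = getnum(row, "a_bh", rownum)
        dbh = getnum(row, "dbh", rownum)
        if a_bh is None and dbh is None:
            drop("missing_size")
            continue
        la = getnum(row, "leaf_area", rownum)
        lm = getnum(row, "leaf_mass", rownum)
        if require_leaf and la is None and lm is None:
            drop("no_leaf_measurement")
            continue
        pft = getval(row, "pft")
        if pft is None:
            habit = (getval(row, "leaf_habit") or "").lower()
            form = (getval(row, "leaf_form") or "").lower()
            h = {"evergreen": "E", "e": "E", "deciduous": "D", "d": "D"}.get(habit)
            f = {"broadleaf": "B", "broadleaved": "B", "b": "B",
                 "conifer": "C", "coniferous": "C", "needleleaf": "C",
                 "c": "C"}.get(form)
            pft = (h + f) if h and f else None
        a_cb = getnum(row, "a_cb", rownum)
        if a_cb is None:
            d_cb = getnum(row, "d_cb", rownum)
            a_cb = area_from_diameter(d_cb) if d_cb else None
        tid = getval(row, "tree_id") or f"row{rownum}"
        try:
            rec = TreeRecord(
                tree_id=tid, species=species, pft=pft, a_bh=a_bh, dbh=dbh,
                height=height, crown_base_height=cb, a_cb_measured=a_cb,
                leaf_area=la, leaf_mass=lm,
            )
        except ValueError:
            drop("invalid_value")
            continue
        records.append(rec)
        report.retained_total += 1
        if pft:
            report.retained_per_pft[pft] = report.retained_per_pft.get(pft, 0) + 1
        if species:
            report.retained_per_species[species] = \
                report.retained_per_species.get(species, 0) + 1

    report.check()
    if report.n_removed:
        log.info("read %d rows from %s: kept %d, removed %s",
                 report.n_input, path.name, report.retained_total, report.removed)
    return records, report


def write_records(path, records: Sequence[TreeRecord], sep: str = ",",
                  digits: int = 10) -> None:
    """Write records in the canonical schema this module reads back."""
    cols = ["tree_id", "species", "pft", "a_bh", "height", "crown_base_height",
            "a_cb", "leaf_area", "leaf_mass"]
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter=sep)
        w.writerow(cols)
        for t in records:
            w.writerow([
                t.tree_id, t.species or "", t.pft or "",
                f"{t.a_bh:.{digits}g}", f"{t.height:.{digits}g}",
                f"{t.crown_base_height:.{digits}g}",
                "" if t.a_cb_measured is None else f"{t.a_cb_measured:.{digits}g}",
                "" if t.leaf_area is None else f"{t.leaf_area:.{digits}g}",
                "" if t.leaf_mass is None else f"{t.leaf_mass:.{digits}g}",
            ])


#: ColumnMap matching what :func:`write_records` emits.
CANONICAL_MAP = ColumnMap(columns={
    "tree_id": "tree_id", "species": "species", "pft": "pft", "a_bh": "a_bh",
    "height": "height", "crown_base_height": "crown_base_height",
    "a_cb": "a_cb", "leaf_area": "leaf_area", "leaf_mass": "leaf_mass",
})
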