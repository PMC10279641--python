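"""Tree-dimension bookkeeping, the qPipe crown-base area estimator, and stem-taper error analysis.

The quasi-pipe (qPipe) estimator approximates the stem cross-sectional area at the
crown base, ``A_CB``, from quantities measurable from the forest floor::

    A_CB_Est = A_BH * R_CROWN

where ``A_BH`` is the stem cross-sectional area at breast height (1.3 m) and
``R_CROWN = L_C / H_>1.3`` is the crown ratio (crown length over stem length above
breast height).  The estimator is exact when the stem between breast height and the
treetop is a paraboloid of revolution with its apex at the treetop; the taper
machinery below quantifies the error for other stem shapes.

Units are fixed: lengths in m, areas in m².  Breast height is fixed at 1.3 m.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

__all__ = [
    "BREAST_HEIGHT",
    "TreeRecord",
    "TaperModel",
    "area_from_diameter",
    "diameter_from_area",
    "crown_ratio",
    "estimate_acb",
    "taper_relative_area",
    "qpipe_relative_error",
    "taper_exponent_from_observation",
]

#: Breast height in metres.  All inclusion filters and the stem-length scale
#: H_>1.3 reference this height; it is deliberately not configurable.
BREAST_HEIGHT = 1.3


class DomainError(ValueError):
    """An input lies outside the domain a geometric operation is defined on."""


def area_from_diameter(d: float) -> float:
    """Cross-sectional area (m²) of a circular stem of diameter ``d`` (m)."""
    if not d > 0:
        raise DomainError(f"diameter must be > 0, got {d!r}")
    return math.pi * d * d / 4.0


def diameter_from_area(a: float) -> float:
    """Diameter (m) of a circular stem with cross-sectional area ``a`` (m²)."""
    if not a > 0:
        raise DomainError(f"area must be > 0, got {a!r}")
    return math.sqrt(4.0 * a / math.pi)


@dataclass
class TreeRecord:
    """One tree's ground-measurable dimensions and optional leaf measurements.

    Parameters
    ----------
    tree_id
        Caller-chosen identifier.
    species, pft
        Species name and plant functional type, one of ``EC, DC, EB, DB``
        (evergreen/deciduous × conifer/broadleaf).  ``pft`` may be ``None``
        for workflows that do not need it (e.g. pooled leaf-area prediction).
    a_bh
        Stem cross-sectional area at breast height, m².  Supply either
        ``a_bh`` or ``dbh`` (m); the area is the canonical representation.
    height
        Total tree height H, m.  Must exceed breast height (1.3 m).
    crown_base_height
        Height of the crown base, m, in ``[1.3, height)``.
    a_cb_measured
        Directly measured crown-base cross-sectional area, m² (optional;
        required only for pipe-model and taper diagnostics).
    leaf_area, leaf_mass
        One-sided / projected leaf area (m²) and leaf dry mass (kg), optional.
    """

    tree_id: str
    species: Optional[str] = None
    pft: Optional[str] = None
    a_bh: Optional[float] = None
    dbh: Optional[float] = None
    height: float = 0.0
    crown_base_height: float = BREAST_HEIGHT
    a_cb_measured: Optional[float] = None
    leaf_area: Optional[float] = None
    leaf_mass: Optional[float] = None

    VALID_PFTS = ("EC", "DC", "EB", "DB")

    def __post_init__(self) -> None:
        if self.a_bh is None:
            if self.dbh is None:
                raise DomainError(f"tree {self.tree_id}: need a_bh or dbh")
            self.a_bh = area_from_diameter(self.dbh)
        elif not self.a_bh > 0:
            raise DomainError(f"tree {self.tree_id}: a_bh must be > 0")
        if self.dbh is None:
            self.dbh = diameter_from_area(self.a_bh)
        if not self.height > BREAST_HEIGHT:
            raise DomainError(
                f"tree {self.tree_id}: height must exceed breast height "
                f"({BREAST_HEIGHT} m), got {self.height}"
            )
        if not BREAST_HEIGHT <= self.crown_base_height < self.height:
            # crown_base == height means a zero crown: R_CROWN = 0 implies a
            # zero leaf amount and breaks the log-scale regressions downstream.
            raise DomainError(
                f"tree {self.tree_id}: crown_base_height must lie in "
                f"[{BREAST_HEIGHT}, height), got {self.crown_base_height} "
                f"with height {self.height}"
            )
        if self.pft is not None and self.pft not in self.VALID_PFTS:
            raise DomainError(
                f"tree {self.tree_id}: pft must be one of {self.VALID_PFTS}, "
                f"got {self.pft!r}"
            )
        for name in ("a_cb_measured", "leaf_area", "leaf_mass"):
            v = getattr(self, name)
            if v is not None and not v > 0:
                raise DomainError(f"tree {self.tree_id}: {name} must be > 0")

    @property
    def stem_length_above_bh(self) -> float:
        """H_>1.3, the stem length above breast height (m)."""
        return self.height - BREAST_HEIGHT

    @property
    def crown_length(self) -> float:
        """L_C = H − crown-base height (m)."""
        return self.height - self.crown_base_height


def crown_ratio(t: TreeRecord) -> float:
    """Crown ratio R_CROWN = L_C / H_>1.3, in (0, 1]."""
    return t.crown_length / t.stem_length_above_bh


def estimate_acb(t: TreeRecord) -> float:
    """qPipe estimate of the crown-base cross-sectional area: A_BH × R_CROWN (m²).

    Exact for a paraboloidal stem with apex at the treetop; never exceeds A_BH.
    """
    return t.a_bh * crown_ratio(t)


@dataclass(frozen=True)
class TaperModel:
    """Relative stem profile ``A = L^(2/X)`` between breast height and treetop.

    ``L`` is the distance from the treetop and ``A`` the cross-sectional area,
    both on relative scales that equal 1 at breast height.  The exponent ``X``
    measures the degree of stem taper: X = 1 is a cone, X = 2 a paraboloid of
    revolution (the qPipe assumption) and X = 3 a cubic solid of revolution.
    """

    exponent_x: float = 2.0

    def __post_init__(self) -> None:
        if not self.exponent_x > 0:
            raise DomainError(f"taper exponent X must be > 0, got {self.exponent_x}")


def taper_relative_area(l: float, m: TaperModel) -> float:
    """Relative stem area ``l^(2/X)`` at relative distance ``l`` from the treetop.

    ``l`` must lie in (0, 1]; the result lies in (0, 1] and equals ``l`` for the
    paraboloid (X = 2).
    """
    if not 0 < l <= 1:
        raise DomainError(f"relative distance must be in (0, 1], got {l}")
    return l ** (2.0 / m.exponent_x)


def qpipe_relative_error(l: float, m: TaperModel) -> float:
    """Ratio A_CB_Est / A_CB for a stem of taper ``m`` with relative crown length ``l``.

    The qPipe estimator assumes a paraboloid (X = 2), so for a true taper
    exponent X the ratio is ``l^(1 − 2/X)``: above 1 (overestimate) when X < 2,
    exactly 1 when X = 2, below 1 (underestimate) when X > 2.  ``l = 1``
    (crown to breast height) gives exactly 1 for every X.
    """
    if not 0 < l <= 1:
        raise DomainError(f"relative crown length must be in (0, 1], got {l}")
    return l ** (1.0 - 2.0 / m.exponent_x)


def taper_exponent_from_observation(l: float, a: float) -> float:
    """Taper exponent X solving ``a = l^(2/X)`` for an observed (l, a) pair.

    ``l`` is the relative crown length L_C / H_>1.3 and ``a`` the observed
    relative area A_CB / A_BH, both strictly inside (0, 1): at 1 the profile
    gives no information and the exponent is undefined.
    """
    if not 0 < l < 1:
        raise DomainError(f"relative crown length must be in (0, 1), got {l}")
    if not 0 < a < 1:
        raise DomainError(f"relative area must be in (0, 1), got {a}")
    return 2.0 * math.log(l) / math.log(a)
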