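"""Stand-level leaf area index and leaf biomass with propagated 95% bounds.

A stand's LAI is the sum of per-tree leaf-area predictions divided by the
ground area; its uncertainty comes from propagating each tree's 95% prediction
interval, treating trees as independent.  Because back-transformed lognormal
intervals are asymmetric, naive quadrature of quantile half-widths misstates
the percentiles of the *sum*; the default propagation therefore converts each
tree's interval into the implied ln-scale (μ, σ), sums the exact first three
moments of the per-tree lognormals, and reads the stand bounds off a shifted
lognormal matched to the total's mean, variance and skewness.  Per-side
quadrature (√Σδ²) and log-scale quadrature are available as alternatives.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .allometry import CoefficientRegistry, PowerLawAllometry, prediction_interval, estimate_tree
from .geometry import TreeRecord, estimate_acb

__all__ = ["Stand", "StandEstimate", "estimate_stand", "compare_methods", "write_report"]

log = logging.getLogger(__name__)

_Z95 = stats.norm.ppf(0.975)


@dataclass
class Stand:
    """A list of trees on a known ground area (m²)."""

    trees: List[TreeRecord]
    area: float

    def __post_init__(self) -> None:
        if not self.area > 0:
            raise ValueError("stand area must be > 0")
        if not self.trees:
            raise ValueError("stand must contain at least one tree")


@dataclass
class StandEstimate:
    """A stand-level quantity with 95% bounds and the per-tree triples behind it.

    ``quantity`` is ``"LAI"`` (m² leaf per m² ground) or ``"leaf_biomass"``
    (kg dry mass per m² ground).
    """

    quantity: str
    point: float
    lower95: float
    upper95: float
    n_trees: int
    area: float
    per_tree: List[Tuple[float, float, float]] = field(default_factory=list)
    method: str = "lognormal"

    def __post_init__(self) -> None:
        if not self.lower95 <= self.point <= self.upper95:
            raise ValueError("bounds must bracket the point estimate")


def _propagate(triples: Sequence[Tuple[float, float, float]], area: float,
               method: str) -> Tuple[float, float, float]:
    los = np.array([t[0] for t in triples])
    pts = np.array([t[1] for t in triples])
    his = np.array([t[2] for t in triples])
    point = pts.sum() / area
    if method == "quadrature":
        # per-side quadrature of arithmetic half-widths
        lo = point - math.sqrt(((pts - los) ** 2).sum()) / area
        hi = point + math.sqrt(((his - pts) ** 2).sum()) / area
        return point, max(lo, 0.0), hi
    if method == "log":
        # delta-method quadrature on the ln of the total: each tree
        # contributes pt_i × (its ln-scale half-width) to Var(ln ΣY)
        total = pts.sum()
        d_lo = np.log(pts / np.maximum(los, 1e-300))
        d_hi = np.log(his / pts)
        w_lo = math.sqrt(((pts * d_lo) ** 2).sum()) / total
        w_hi = math.sqrt(((pts * d_hi) ** 2).sum()) / total
        return point, point * math.exp(-w_lo), point * math.exp(w_hi)
    if method != "lognormal":
        raise ValueError(f"unknown propagation method {method!r}")
    # moment-matched lognormal summation: each tree's interval exp(μ ± z σ)
    # gives (μ, σ) on the ln scale, i.e. a lognormal whose first three central
    # moments are known in closed form.  Independence lets the moments of the
    # stand total be summed, and the bounds are the 2.5/97.5 percentiles of a
    # shifted lognormal matched to (mean, variance, skewness) of the total —
    # exact for a single tree and for the many-equal-trees normal limit.
    sigmas = np.log(his / np.maximum(los, 1e-300)) / (2.0 * _Z95)
    mus = 0.5 * np.log(his * los)
    m = np.exp(mus + sigmas ** 2 / 2.0)
    w = np.exp(sigmas ** 2)
    v = m * m * (w - 1.0)
    mu3 = m ** 3 * (w - 1.0) ** 2 * (w + 2.0)
    M, V, K3 = m.sum(), v.sum(), mu3.sum()
    if V <= 0:
        return point, point, point
    skew = K3 / V ** 1.5
    # solve (w_s + 2)√(w_s − 1) = skew for the matching ln-scale variance:
    # with t = √(w_s − 1) this is the depressed cubic t³ + 3t − skew = 0
    roots = np.roots([1.0, 0.0, 3.0, -skew])
    real = roots[np.abs(roots.imag) < 1e-9].real  # cubic is monotone: one real root
    t = max(float(real.max()), 1e-12)
    s2 = math.log(1.0 + t * t)
    m_ln = math.sqrt(V / (t * t))       # mean of the lognormal component
    shift = M - m_ln
    mu_s = math.log(m_ln) - s2 / 2.0
    lo = (shift + math.exp(mu_s - _Z95 * math.sqrt(s2))) / area
    hi = (shift + math.exp(mu_s + _Z95 * math.sqrt(s2))) / area
    # bounds describe the distribution of the total; keep them bracketing the
    # (CF-corrected) point estimate in the degenerate near-zero-width case
    return point, min(lo, point), max(hi, point)


def estimate_stand(s: Stand, registry: CoefficientRegistry, quantity: str = "LAI",
                   predictor: str = "A_CB_Est", method: str = "lognormal",
                   ) -> StandEstimate:
    """Stand LAI (``quantity="LAI"``) or leaf biomass per ground area.

    Per-tree predictions with 95% intervals come from the registry (pooled LA
    equation, or the per-PFT LM equations for biomass); the point estimate is
    Σ point_i / area and the bounds are propagated per ``method``
    ("lognormal" default, "quadrature", or "log").  Any invalid tree aborts
    with an error naming its ``tree_id``.
    """
    if quantity not in ("LAI", "leaf_biomass"):
        raise ValueError(f"quantity must be 'LAI' or 'leaf_biomass', got {quantity!r}")
    response = "LA" if quantity == "LAI" else "LM"
    triples = []
    for t in s.trees:
        try:
            triples.append(estimate_tree(t, registry, response, predictor))
        except (ValueError, KeyError) as e:
            raise ValueError(f"tree {t.tree_id}: {e}") from e
    point, lo, hi = _propagate(triples, s.area, method)
    return StandEstimate(quantity=quantity, point=point, lower95=lo, upper95=hi,
                         n_trees=len(s.trees), area=s.area, per_tree=triples,
                         method=method)


def estimate_stand_with(s: Stand, allom: PowerLawAllometry, quantity: str = "LAI",
                        method: str = "lognormal") -> StandEstimate:
    """Like :func:`estimate_stand` but with one explicit allometry for all trees."""
    triples = []
    for t in s.trees:
        if allom.predictor == "A_CB":
            if t.a_cb_measured is None:
                raise ValueError(f"tree {t.tree_id}: no measured A_CB for a "
                                 "pipe-model allometry")
            x = t.a_cb_measured
        else:
            x = estimate_acb(t)
        triples.append(prediction_interval(allom, allom.pi, x))
    point, lo, hi = _propagate(triples, s.area, method)
    quantity = quantity if quantity else ("LAI" if allom.response == "LA" else "leaf_biomass")
    return StandEstimate(quantity=quantity, point=point, lower95=lo, upper95=hi,
                         n_trees=len(s.trees), area=s.area, per_tree=triples,
                         method=method)


def compare_methods(s: Stand, methods: Sequence[Tuple[str, PowerLawAllometry]],
                    quantity: str = "LAI", method: str = "lognormal",
                    ) -> Dict[str, StandEstimate]:
    """One StandEstimate per named allometric method, on identical trees.

    ``methods`` is a sequence of (label, allometry); entries whose predictor is
    measured A_CB require ``a_cb_measured`` on every tree.  The returned dict
    preserves order; pairwise overlap of the 95% bounds can be read directly
    off the estimates.
    """
    out: Dict[str, StandEstimate] = {}
    for label, allom in methods:
        out[label] = estimate_stand_with(s, allom, quantity=quantity, method=method)
    return out


def intervals_overlap(a: StandEstimate, b: StandEstimate) -> bool:
    return a.lower95 <= b.upper95 and b.lower95 <= a.upper95


def exclude_invalid_trees(trees: Sequence[TreeRecord]) -> List[TreeRecord]:
    """Drop trees that cannot be aggregated, logging the count.

    TreeRecord construction already rejects zero-crown (dead/dying) trees, so
    lists built through the io module never need this; it exists for callers
    assembling records by other means.
    """
    kept = [t for t in trees if t.crown_base_height < t.height]
    dropped = len(trees) - len(kept)
    if dropped:
        log.info("excluded %d zero-crown/invalid trees from aggregation", dropped)
    return kept


def write_report(path, estimates: Dict[str, StandEstimate], digits: int = 6,
                 sep: str = "\t") -> None:
    """Write one row per method: quantity, point, lower, upper, n_trees, area."""
    cols = ["method", "quantity", "point", "lower95", "upper95", "n_trees", "area"]
    with open(path, "w") as fh:
        fh.write(sep.join(cols) + "\n")
        for label, e in estimates.items():
            row = [label, e.quantity, f"{e.point:.{digits}g}", f"{e.lower95:.{digits}g}",
                   f"{e.upper95:.{digits}g}", str(e.n_trees), f"{e.area:.{digits}g}"]
            fh.write(sep.join(row) + "\n")
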