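"""Power-law prediction equations Y = CF × Elevation × X^Slope with 95% prediction intervals.

A :class:`PowerLawAllometry` predicts per-tree leaf area (LA, m²) or leaf dry
mass (LM, kg) from a crown-base stem area (measured A_CB or the qPipe estimate
A_CB_Est, m²).  The shipped :class:`CoefficientRegistry` carries the global
coefficients fitted across 962 trees of 159 species spanning tropical to
boreal forests: one pooled equation for LA (plant functional type does not
improve the prediction model) and one equation per PFT for LM (the lines
separate clearly by PFT).  Each entry carries an approximation of its 95%
prediction interval, either a quadratic in u = ln(predictor) or the exact
least-squares interval form.

The same machinery fits site-specific allometries from local tree records via
:func:`fit_allometry`.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import yaml

from . import regression as reg
from .geometry import TreeRecord, estimate_acb

__all__ = [
    "PowerLawAllometry",
    "PIApproximation",
    "CoefficientRegistry",
    "load_registry",
    "default_registry",
    "predict",
    "prediction_interval",
    "estimate_tree",
    "fit_allometry",
]


class ExtrapolationWarning(UserWarning):
    """Prediction requested outside the allometry's calibrated predictor range."""


@dataclass(frozen=True)
class PIApproximation:
    """95% prediction-interval half-width ΔPI for ln(response) as a function of u = ln(predictor).

    ``form="quadratic"``: ΔPI = c0 + c1·u + c2·u² (the approximation published
    for the mixed-model fits).  ``form="ls"``: the exact ordinary
    least-squares interval ΔPI = c0·c1·sqrt(1 + 1/c2 + (u − c3)²/c4), where
    c0 is the t quantile, c1 the residual sd, c2 = n, c3 the mean of u and
    c4 = Σ(u − ū)².  ``residual_se`` is the reported goodness of the
    approximating fit; it is stored but plays no role in prediction.
    """

    form: str
    c0: float
    c1: float
    c2: float
    c3: Optional[float] = None
    c4: Optional[float] = None
    residual_se: Optional[float] = None

    def __post_init__(self) -> None:
        if self.form not in ("quadratic", "ls"):
            raise ValueError(f"unknown PI form {self.form!r}")
        if self.form == "ls" and (self.c3 is None or self.c4 is None):
            raise ValueError("ls form needs all of c0..c4")

    def halfwidth(self, u) -> np.ndarray:
        u = np.asarray(u, dtype=float)
        if self.form == "quadratic":
            d = self.c0 + self.c1 * u + self.c2 * u * u
        else:
            d = self.c0 * self.c1 * np.sqrt(1.0 + 1.0 / self.c2
                                            + (u - self.c3) ** 2 / self.c4)
        if np.any(d < 0):
            raise ValueError("PI approximation produced a negative half-width; "
                             "check its coefficients")
        return d


@dataclass(frozen=True)
class PowerLawAllometry:
    """One prediction equation Y = CF × Elevation × X^Slope.

    ``elevation`` is the (uncorrected) response at predictor = 1 m²; ``cf`` is
    the lognormal bias-correction factor applied to point predictions.
    ``data_range`` gives soft bounds (m²) of the predictor range the equation
    was calibrated on; predictions outside it warn but proceed.
    """

    key: str
    response: str                  # "LA" or "LM"
    predictor: str                 # "A_CB" or "A_CB_Est"
    scope: str                     # "pooled", "per-PFT" or "site-specific"
    elevation: float
    slope: float
    cf: float = 1.0
    n: Optional[int] = None
    pft: Optional[str] = None
    pi: Optional[PIApproximation] = None
    data_range: Optional[Tuple[float, float]] = None

    def __post_init__(self) -> None:
        if self.elevation <= 0:
            raise ValueError("elevation must be > 0")
        if self.cf < 1.0 - 1e-12:
            raise ValueError("CF must be ≥ 1")


def predict(a: PowerLawAllometry, x: float) -> float:
    """CF-corrected point prediction CF × Elevation × x^Slope at predictor x (m²)."""
    x = float(x)
    if not x > 0:
        raise ValueError(f"predictor must be > 0 m², got {x}")
    return a.cf * a.elevation * x ** a.slope


def prediction_interval(a: PowerLawAllometry, p: Optional[PIApproximation],
                        x: float, cf_in_bounds: bool = False
                        ) -> Tuple[float, float, float]:
    """(lower, point, upper) at predictor ``x`` using the interval approximation ``p``.

    Bounds are exp(ln Ŷ ± ΔPI) around the *uncorrected* ln-scale prediction
    (the regression's natural scale); the point estimate is CF-corrected.  Set
    ``cf_in_bounds=True`` to centre the interval on the corrected prediction
    instead.  Predictions outside ``a.data_range`` raise
    :class:`ExtrapolationWarning` but are returned.
    """
    x = float(x)
    if not x > 0:
        raise ValueError(f"predictor must be > 0 m², got {x}")
    if p is None:
        p = a.pi
    if p is None:
        raise ValueError(f"allometry {a.key!r} has no prediction-interval approximation")
    if a.data_range is not None and not (a.data_range[0] <= x <= a.data_range[1]):
        warnings.warn(
            f"{a.key}: predictor {x:g} m² lies outside the calibrated range "
            f"[{a.data_range[0]:g}, {a.data_range[1]:g}] m²; extrapolating",
            ExtrapolationWarning, stacklevel=2,
        )
    u = math.log(x)
    ln_y = math.log(a.elevation) + a.slope * u
    delta = float(p.halfwidth(u))
    centre = ln_y + (math.log(a.cf) if cf_in_bounds else 0.0)
    point = a.cf * math.exp(ln_y)
    return (math.exp(centre - delta), point, math.exp(centre + delta))


@dataclass
class CoefficientRegistry:
    """Keyed collection of allometries; ships with the published global coefficients.

    Leaf area uses a single pooled equation (key ``qpipe_la_pooled`` for the
    qPipe predictor, ``pipe_la_pooled`` for measured A_CB); leaf mass uses one
    qPipe equation per plant functional type (``qpipe_lm_EC`` …).
    """

    entries: Dict[str, PowerLawAllometry] = field(default_factory=dict)

    def __getitem__(self, key: str) -> PowerLawAllometry:
        return self.entries[key]

    def __contains__(self, key: str) -> bool:
        return key in self.entries

    def add(self, a: PowerLawAllometry) -> None:
        self.entries[a.key] = a

    def for_tree(self, response: str, predictor: str = "A_CB_Est",
                 pft: Optional[str] = None) -> PowerLawAllometry:
        """Select the entry used to predict ``response`` for one tree."""
        if response == "LA":
            key = "qpipe_la_pooled" if predictor == "A_CB_Est" else "pipe_la_pooled"
            if key not in self.entries:
                raise KeyError(f"registry has no pooled LA entry {key!r}")
            return self.entries[key]
        if response == "LM":
            if pft not in TreeRecord.VALID_PFTS:
                raise KeyError(
                    f"leaf-mass prediction needs a valid PFT "
                    f"(one of {TreeRecord.VALID_PFTS}), got {pft!r}"
                )
            key = f"qpipe_lm_{pft}"
            if key not in self.entries:
                raise KeyError(f"registry has no LM entry for PFT {pft!r}")
            return self.entries[key]
        raise ValueError(f"response must be 'LA' or 'LM', got {response!r}")

    def to_yaml(self, path) -> None:
        out = {}
        for k, a in self.entries.items():
            e = {
                "response": a.response, "predictor": a.predictor, "scope": a.scope,
                "elevation": a.elevation, "slope": a.slope, "cf": a.cf,
            }
            if a.n is not None:
                e["n"] = a.n
            if a.pft is not None:
                e["pft"] = a.pft
            if a.data_range is not None:
                e["data_range"] = list(a.data_range)
            if a.pi is not None:
                pi = {"form": a.pi.form, "c0": a.pi.c0, "c1": a.pi.c1, "c2": a.pi.c2}
                for name in ("c3", "c4", "residual_se"):
                    v = getattr(a.pi, name)
                    if v is not None:
                        pi[name] = v
                e["pi"] = pi
            out[k] = e
        with open(path, "w") as fh:
            yaml.safe_dump({"allometries": out}, fh, sort_keys=False)


def _entry_from_dict(key: str, e: dict) -> PowerLawAllometry:
    pi = None
    if "pi" in e:
        d = dict(e["pi"])
        pi = PIApproximation(
            form=d["form"], c0=d["c0"], c1=d["c1"], c2=d["c2"],
            c3=d.get("c3"), c4=d.get("c4"), residual_se=d.get("residual_se"),
        )
    dr = e.get("data_range")
    return PowerLawAllometry(
        key=key, response=e["response"], predictor=e["predictor"],
        scope=e.get("scope", "site-specific"), elevation=e["elevation"],
        slope=e["slope"], cf=e.get("cf", 1.0), n=e.get("n"), pft=e.get("pft"),
        pi=pi, data_range=None if dr is None else (float(dr[0]), float(dr[1])),
    )


def load_registry(path) -> CoefficientRegistry:
    """Load a registry from a YAML file (same schema the package ships)."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    regy = CoefficientRegistry()
    for key, e in doc["allometries"].items():
        regy.add(_entry_from_dict(key, e))
    return regy


def default_registry() -> CoefficientRegistry:
    """The registry of published global coefficients shipped with the package."""
    with resources.files("qpipe.data").joinpath("global_registry.yaml").open() as fh:
        doc = yaml.safe_load(fh)
    regy = CoefficientRegistry()
    for key, e in doc["allometries"].items():
        regy.add(_entry_from_dict(key, e))
    return regy


def estimate_tree(t: TreeRecord, registry: CoefficientRegistry, response: str,
                  predictor: str = "A_CB_Est") -> Tuple[float, float, float]:
    """(lower, point, upper) prediction of LA (m²) or LM (kg) for one tree.

    The predictor value is the qPipe estimate A_CB_Est computed from the
    tree's dimensions (or the measured A_CB when ``predictor="A_CB"``); LA
    uses the pooled equation regardless of PFT, LM the tree's PFT equation.
    """
    if predictor == "A_CB_Est":
        x = estimate_acb(t)
    elif predictor == "A_CB":
        if t.a_cb_measured is None:
            raise ValueError(f"tree {t.tree_id}: no measured A_CB")
        x = t.a_cb_measured
    else:
        raise ValueError(f"predictor must be 'A_CB' or 'A_CB_Est', got {predictor!r}")
    a = registry.for_tree(response, predictor, t.pft)
    return prediction_interval(a, a.pi, x)


def _records_to_dataset(records: Sequence[TreeRecord], response: str,
                        predictor: str) -> reg.LogLogDataset:
    xs, ys, pfts, sps = [], [], [], []
    for t in records:
        y = t.leaf_area if response == "LA" else t.leaf_mass
        if y is None:
            continue
        if predictor == "A_CB":
            if t.a_cb_measured is None:
                continue
            x = t.a_cb_measured
        else:
            x = estimate_acb(t)
        xs.append(math.log(x))
        ys.append(math.log(y))
        pfts.append(t.pft)
        sps.append(t.species)
    if len(xs) < 3:
        raise reg.DegenerateDataError(
            f"fewer than 3 records carry {response} and {predictor}"
        )
    group = None if any(p is None for p in pfts) else np.array(pfts)
    species = None if any(s is None for s in sps) else np.array(sps)
    return reg.LogLogDataset(np.array(xs), np.array(ys), group, species)


def fit_allometry(records: Sequence[TreeRecord], response: str,
                  predictor: str = "A_CB_Est", scope: str = "site-specific",
                  key: Optional[str] = None, pft: Optional[str] = None,
                  grubbs_alpha: Optional[float] = 0.05,
                  min_records: int = 10) -> PowerLawAllometry:
    """Fit a site-specific power-law allometry with AIC model selection.

    Candidate Model-I fits (OLS; species random intercept when ≥ 2 species)
    are compared by AIC; residual-based Grubbs outlier removal (two-sided,
    ``grubbs_alpha``) is applied once before the final fit (pass ``None`` to
    disable).  The returned allometry carries the lognormal correction factor
    and a fitted prediction-interval approximation: the exact least-squares
    form when OLS wins, otherwise a quadratic least-squares fit to the exact
    pointwise mixed-model interval across the observed predictor range.
    """
    if pft is not None:
        records = [t for t in records if t.pft == pft]
    d = _records_to_dataset(records, response, predictor)
    if d.n < min_records:
        raise reg.DegenerateDataError(
            f"need ≥ {min_records} usable records, got {d.n}"
        )
    if grubbs_alpha is not None:
        resid = d.y - np.polyval(np.polyfit(d.x, d.y, 1), d.x)
        gres = reg.grubbs_filter(resid, alpha=grubbs_alpha)
        if gres.n_removed:
            d = d.subset(gres.kept_indices)

    candidates: List[reg.ModelOneFit] = [reg.fit_ols(d)]
    if d.species is not None and len(set(d.species.tolist())) >= 2:
        try:
            candidates.append(reg.fit_random_intercept(d))
        except reg.ConvergenceError:
            pass
    fit = reg.select_model(candidates)

    if fit.kind == "ols":
        from scipy import stats as _st
        pi = PIApproximation(
            form="ls", c0=float(_st.t.ppf(0.975, fit.n - 2)), c1=fit.residual_sd,
            c2=float(fit.n), c3=fit.x_mean, c4=fit.x_ss,
        )
    else:
        # quadratic least-squares approximation to the exact pointwise ΔPI
        grid = np.linspace(d.x.min(), d.x.max(), 200)
        c2_, c1_, c0_ = np.polyfit(grid, fit.pi_halfwidth(grid), 2)
        exact = fit.pi_halfwidth(grid)
        approx = c0_ + c1_ * grid + c2_ * grid ** 2
        rse = float(np.sqrt(np.mean((approx - exact) ** 2)))
        pi = PIApproximation(form="quadratic", c0=float(c0_), c1=float(c1_),
                             c2=float(c2_), residual_se=rse)

    return PowerLawAllometry(
        key=key or f"{scope}_{response.lower()}_{predictor.lower()}",
        response=response, predictor=predictor, scope=scope,
        elevation=fit.elevation, slope=fit.slope, cf=fit.cf, n=fit.n, pft=pft,
        pi=pi, data_range=(float(np.exp(d.x.min())), float(np.exp(d.x.max()))),
    )
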