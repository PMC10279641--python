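"""Seeded generator of synthetic trees and stands with known ground truth.

The generator emulates the structure of a multi-species, multi-PFT tree
inventory suitable for pipe/qPipe allometry: a power-law relation between the
true crown-base stem area A_CB and leaf area with slope ≈ 1, lognormal
residual scatter, Gaussian ln-scale species intercept offsets, per-tree stem
taper exponents X centred on the paraboloid value 2, and a leaf-mass-per-area
(LMA) that rises with tree height so that leaf-mass allometric slopes exceed
leaf-area slopes — the mechanism behind the finding that the classical
pipe-model proportionality holds on a leaf-area basis but not a leaf-mass
basis.

Defaults mirror the conditions of the global compiled dataset where they are
stated (ln-scale residual sd 0.385, the value implied by the published
correction factor 1.077; LA slope 1; multi-decade size spread) and otherwise
sit at values typical of closed-canopy forest inventories.  Every dataset is
emitted together with its generating truth; a single seed drives a splittable
per-tree stream so any subset of a dataset is reproducible on its own.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd

from .geometry import BREAST_HEIGHT, TaperModel, TreeRecord, taper_relative_area
from .stand import Stand

__all__ = ["SimulationConfig", "GroundTruth", "generate_dataset", "generate_stand"]


@dataclass
class SimulationConfig:
    """Parameters of the synthetic inventory generator.

    Heights are lognormal (offset above breast height), crown ratios
    Beta-distributed, taper exponents lognormal around ``taper_median`` — all
    chosen for positivity and realistic right skew.  ``gamma_lma > 0`` makes
    tree-level LMA rise with height as (H/href)^γ, which steepens the leaf-mass
    slope relative to the leaf-area slope.
    """

    n_trees: int = 500
    n_species: int = 30
    seed: int = 0
    # height H = 1.3 + LogNormal(mu, sd), m
    height_ln_mu: float = 2.5          # median ≈ 13.5 m above breast height
    height_ln_sd: float = 0.45
    # dbh correlated with height through a shared latent size factor
    dbh_ln_mu: float = -1.9            # median ≈ 0.15 m
    dbh_ln_sd: float = 0.55
    size_corr: float = 0.9
    # crown ratio R_CROWN ~ Beta(a, b), in (0, 1]
    crown_ratio_a: float = 5.0
    crown_ratio_b: float = 2.5
    # stem taper exponent X ~ LogNormal(ln(taper_median), taper_ln_sd)
    taper_median: float = 2.0
    taper_ln_sd: float = 0.15
    # true leaf-area allometry LA = elevation * A_CB^slope * lognormal error
    la_elevation: float = 3000.0       # m² leaf at A_CB = 1 m²
    la_slope: float = 1.0
    residual_sd: float = 0.385         # ln-scale; implies CF ≈ 1.077
    species_sd: float = 0.3            # ln-scale species intercept sd
    # LMA model: tree LMA = base_lma * (H / href)^gamma  (kg m⁻²)
    base_lma: float = 0.100
    href: float = 15.0
    gamma_lma: float = 0.3

    def __post_init__(self) -> None:
        if self.n_trees < 1 or self.n_species < 1:
            raise ValueError("n_trees and n_species must be ≥ 1")
        for name in ("height_ln_sd", "dbh_ln_sd", "taper_ln_sd",
                     "residual_sd", "species_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be ≥ 0")
        if not (self.crown_ratio_a > 0 and self.crown_ratio_b > 0):
            raise ValueError("crown ratio Beta parameters must be > 0")
        if self.gamma_lma < 0:
            raise ValueError("gamma_lma must be ≥ 0")
        if not -1 <= self.size_corr <= 1:
            raise ValueError("size_corr must be in [-1, 1]")
        if self.base_lma <= 0 or self.href <= 0 or self.la_elevation <= 0:
            raise ValueError("base_lma, href and la_elevation must be > 0")


_PFTS = ("EB", "EC", "DB", "DC")


@dataclass
class GroundTruth:
    """Everything the generator knew: config, species effects, per-tree truth."""

    config: SimulationConfig
    species_offsets: dict           # species -> ln-scale intercept offset
    species_pft: dict               # species -> PFT
    per_tree: pd.DataFrame          # tree_id, species, taper_x, a_cb_true, lma, noise…

    def to_frame(self) -> pd.DataFrame:
        return self.per_tree


def _tree_streams(seed: int, n: int) -> List[np.random.Generator]:
    """One independent, splittable stream per tree from a single root seed."""
    root = np.random.SeedSequence(seed)
    return [np.random.Generator(np.random.Philox(s)) for s in root.spawn(n)]


def generate_dataset(cfg: SimulationConfig) -> Tuple[List[TreeRecord], GroundTruth]:
    """Draw ``cfg.n_trees`` synthetic trees; return records plus the generating truth.

    Each record carries the ground-measurable dimensions, the *true* crown-base
    area as ``a_cb_measured`` (derived from the tree's own taper exponent via
    the relative taper curve), and the generated leaf area and leaf mass.
    Deterministic for a fixed ``cfg.seed``.
    """
    root = np.random.SeedSequence(cfg.seed)
    sp_rng = np.random.Generator(np.random.Philox(root.spawn(1)[0]))
    species_names = [f"sp{i:03d}" for i in range(cfg.n_species)]
    offsets = dict(zip(species_names,
                       sp_rng.normal(0.0, cfg.species_sd, cfg.n_species)))
    pfts = dict(zip(species_names,
                    [_PFTS[i % len(_PFTS)] for i in range(cfg.n_species)]))

    streams = _tree_streams(cfg.seed + 1, cfg.n_trees)
    records: List[TreeRecord] = []
    rows = []
    for i, rng in enumerate(streams):
        sp = species_names[int(rng.integers(cfg.n_species))]
        z = rng.normal()
        h_above = math.exp(cfg.height_ln_mu + cfg.height_ln_sd * z)
        height = BREAST_HEIGHT + h_above
        eps_d = rng.normal()
        dbh = math.exp(cfg.dbh_ln_mu + cfg.dbh_ln_sd *
                       (cfg.size_corr * z + math.sqrt(1 - cfg.size_corr ** 2) * eps_d))
        a_bh = math.pi * dbh * dbh / 4.0
        # crown ratio strictly inside (0, 1); Beta draws of exactly 0/1 are
        # astronomically unlikely but clipped for safety
        rc = float(np.clip(rng.beta(cfg.crown_ratio_a, cfg.crown_ratio_b),
                           1e-6, 1 - 1e-9))
        crown_base = height - rc * h_above
        taper_x = math.exp(math.log(cfg.taper_median) + cfg.taper_ln_sd * rng.normal())
        # true crown-base area from the tree's own taper curve; the qPipe
        # estimate a_bh*rc corresponds to assuming taper_x = 2
        a_cb_true = a_bh * taper_relative_area(rc, TaperModel(taper_x))
        noise = rng.normal(0.0, cfg.residual_sd)
        la = (cfg.la_elevation * a_cb_true ** cfg.la_slope
              * math.exp(offsets[sp] + noise))
        lma = cfg.base_lma * (height / cfg.href) ** cfg.gamma_lma
        lm = lma * la
        tid = f"t{i:05d}"
        records.append(TreeRecord(
            tree_id=tid, species=sp, pft=pfts[sp], a_bh=a_bh, height=height,
            crown_base_height=crown_base, a_cb_measured=a_cb_true,
            leaf_area=la, leaf_mass=lm,
        ))
        rows.append(dict(tree_id=tid, species=sp, pft=pfts[sp], taper_x=taper_x,
                         a_bh=a_bh, crown_ratio=rc, a_cb_true=a_cb_true,
                         lma=lma, ln_noise=noise, species_offset=offsets[sp],
                         leaf_area=la, leaf_mass=lm))
    truth = GroundTruth(config=cfg, species_offsets=offsets, species_pft=pfts,
                        per_tree=pd.DataFrame(rows))
    return records, truth


def generate_stand(cfg: SimulationConfig, area: float) -> Tuple[Stand, GroundTruth]:
    """A synthetic :class:`Stand` of ``cfg.n_trees`` trees on ``area`` m²."""
    if not area > 0:
        raise ValueError("area must be > 0")
    records, truth = generate_dataset(cfg)
    return Stand(trees=records, area=area), truth
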