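"""Synthetic data with the statistical structure the pipeline assumes.

Four generators, all driven by one seeded :class:`SimulationConfig`:

* birth–death phylogenies with tips ``sp001…``;
* log₁₀-scale allometric traits: the predictor evolves by Brownian motion
  on the tree, the response is intercept + slope·predictor plus a residual
  drawn jointly multivariate-normal with covariance σ²V(λ) — exactly the
  generating model PGLS assumes, so λ recovery is a meaningful test — with
  an optional planted "exceptional" species shifted by an additive
  log-scale offset; values are exported on the raw (antilog) scale so the
  pipeline's own log₁₀ step is exercised;
* two-species per-specimen brain measurements with lognormal noise around
  configurable species means (defaults mirror the vulture contrast: a
  focal species with ~4× the reference's olfactory bulb on a ~20% smaller
  brain);
* 3-D cell fields of known population size, sectioned and frame-sampled
  under a fractionator design with uniformly random offsets (the
  systematic-uniform-random condition the estimator's unbiasedness needs).

Default allometric parameters sit inside the ranges the avian brain-region
fits span (slopes ≈0.4–0.9, λ ≈0.27–0.95).
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field, replace

import dendropy
import numpy as np
import pandas as pd
from scipy import linalg

from .errors import ValidationError
from .stereology import FractionatorDesign
from .trees import PhyloTree
from .allometry import TraitTable

__all__ = ["SimulationConfig", "simulate_tree", "simulate_tree_set",
           "simulate_allometric_traits", "simulate_two_species_specimens",
           "simulate_cell_field", "CellFieldSample"]


#: reported per-species means used as defaults for the two-species generator
_DEFAULT_MEANS = {
    "focal": {"whole_brain": 9211.97, "telencephalon": 6154.25,
              "optic_tectum": 222.96, "nucleus_rotundus": 13.98,
              "entopallium": 100.25, "olfactory_bulb": 224.87,
              "mitral_cells": 162565.0},
    "reference": {"whole_brain": 11579.22, "telencephalon": 8113.36,
                  "optic_tectum": 219.09, "nucleus_rotundus": 15.79,
                  "entopallium": 129.11, "olfactory_bulb": 54.28,
                  "mitral_cells": 86550.0},
}


@dataclass
class SimulationConfig:
    """All knobs for the synthetic generators; ``seed`` fixes everything."""

    seed: int = 0
    # tree simulation
    n_tips: int = 100
    birth_rate: float = 1.0
    death_rate: float = 0.0
    # allometric trait model (log10 scale)
    slope: float = 0.9
    intercept: float = -2.2
    sigma2: float = 0.05
    lam: float = 0.92
    predictor_root: float = 3.5   # log10 mm³, a mid-sized avian brain
    predictor_rate: float = 0.3   # Brownian rate of the predictor
    response_name: str = "olfactory_bulb"
    predictor_name: str = "whole_brain"
    outlier_species: str | None = None
    outlier_offset: float = 0.0   # additive, log10 units
    # two-species specimen generator
    specimens_per_species: int = 3
    specimen_noise_cv: float = 0.08
    ob_enlargement: float = 4.0
    # stereology field
    true_n: int = 10_000
    field_radius_um: float = 500.0
    cut_thickness_um: float = 40.0
    design: FractionatorDesign = field(default_factory=FractionatorDesign)

    def __post_init__(self):
        if self.sigma2 <= 0:
            raise ValidationError("sigma2 must be positive")
        if not (0.0 <= self.lam <= 1.0):
            raise ValidationError("lambda must lie in [0, 1]")

    def with_seed(self, seed: int) -> "SimulationConfig":
        return replace(self, seed=seed)


def _tip_label(i: int) -> str:
    return f"sp{i + 1:03d}"


def simulate_tree(config: SimulationConfig) -> PhyloTree:
    """One seeded birth–death tree with ``config.n_tips`` extant tips."""
    if config.n_tips < 3:
        raise ValidationError("need at least 3 tips")
    rng = random.Random(config.seed)
    last_exc = None
    for attempt in range(100):
        try:
            t = dendropy.simulate.treesim.birth_death_tree(
                birth_rate=config.birth_rate,
                death_rate=config.death_rate,
                num_extant_tips=config.n_tips,
                rng=rng)
            break
        except dendropy.simulate.treesim.TreeSimTotalExtinctionException as exc:
            last_exc = exc
    else:
        raise ValidationError(
            f"all lineages went extinct in 100 attempts: {last_exc}")
    # the simulator stops exactly at the n-th speciation, leaving a
    # zero-length cherry (a singular Brownian covariance); run the clock
    # on for an exponential waiting time so all terminal branches are >0
    extra = rng.expovariate(config.n_tips * config.birth_rate)
    for i, leaf in enumerate(t.leaf_node_iter()):
        leaf.taxon.label = _tip_label(i)
        leaf.edge.length = (leaf.edge.length or 0.0) + extra
    return PhyloTree(t)


def simulate_tree_set(config: SimulationConfig, n_trees: int
                      ) -> list[PhyloTree]:
    """A set of independent seeded trees sharing the same tip labels."""
    return [simulate_tree(config.with_seed(config.seed + 7919 * (k + 1)))
            for k in range(n_trees)]


def simulate_allometric_traits(tree: PhyloTree,
                               config: SimulationConfig) -> TraitTable:
    """Raw-scale trait table simulated under the PGLS generating model."""
    order = sorted(tree.tip_labels)
    _, C = tree.shared_path_matrix(order=order)
    n = len(order)
    diag = np.diag(C).copy()
    V = C * config.lam
    np.fill_diagonal(V, diag)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    jitter = 1e-12 * max(np.max(diag), 1.0) * np.eye(n)
    Lx = linalg.cholesky(config.predictor_rate * C + jitter, lower=True)
    x = config.predictor_root + Lx @ rng.standard_normal(n)
    Lr = linalg.cholesky(config.sigma2 * V + jitter, lower=True)
    resid = Lr @ rng.standard_normal(n)
    y = config.intercept + config.slope * x + resid
    if config.outlier_species is not None:
        if config.outlier_species not in order:
            raise ValidationError(
                f"outlier species {config.outlier_species!r} not a tip")
        y[order.index(config.outlier_species)] += config.outlier_offset
    df = pd.DataFrame({
        "species": order,
        config.predictor_name: 10.0 ** x,
        config.response_name: 10.0 ** y,
    })
    return TraitTable(df)


def simulate_two_species_specimens(config: SimulationConfig, *,
                                   means: dict | None = None,
                                   focal: str = "focal_species",
                                   reference: str = "reference_species"
                                   ) -> pd.DataFrame:
    """Wide per-specimen volume table for a two-species contrast.

    Each specimen's measures are the species means perturbed by
    multiplicative lognormal noise with coefficient of variation
    ``specimen_noise_cv``. The focal species' olfactory bulb mean is the
    reference's scaled by ``ob_enlargement`` when default means are used.
    """
    if config.specimens_per_species < 2:
        raise ValidationError("need >= 2 specimens per species")
    if means is None:
        means = {k: dict(v) for k, v in _DEFAULT_MEANS.items()}
        means["focal"]["olfactory_bulb"] = (
            means["reference"]["olfactory_bulb"] * config.ob_enlargement)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    cv = config.specimen_noise_cv
    sigma_ln = np.sqrt(np.log1p(cv ** 2))
    rows = []
    for species_key, label in (("focal", focal), ("reference", reference)):
        mu = means[species_key]
        for i in range(config.specimens_per_species):
            row = {"specimen": f"{label}_{i + 1}", "species": label}
            for measure, m in mu.items():
                noise = (np.exp(sigma_ln * rng.standard_normal()
                                - sigma_ln ** 2 / 2.0) if cv > 0 else 1.0)
                row[measure] = m * noise
            # independent noise can (rarely) push a sub-region above the
            # whole-brain draw; cap so every specimen stays anatomically
            # coherent
            if "whole_brain" in row:
                for measure in row:
                    if measure not in ("specimen", "species", "whole_brain",
                                       "mitral_cells"):
                        row[measure] = min(row[measure],
                                           0.95 * row["whole_brain"])
            rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class CellFieldSample:
    """Tallies obtained by sectioning and frame-sampling a known field."""

    tallies: np.ndarray = field(repr=False)
    design: FractionatorDesign = field(repr=False, default=None)
    true_n: int = 0
    n_sections: int = 0


def simulate_cell_field(config: SimulationConfig) -> CellFieldSample:
    """Place ``true_n`` cells uniformly in a sphere, cut it into sections
    of ``cut_thickness_um``, count every k-th section through frames on a
    systematic grid; section series and grid carry uniformly random
    (seeded) offsets so the fractionator estimate is unbiased."""
    if config.true_n < 1:
        raise ValidationError("true_n must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 3]))
    r = config.field_radius_um
    pts = rng.uniform(-r, r, size=(int(config.true_n * 2.2), 3))
    pts = pts[np.sum(pts ** 2, axis=1) <= r ** 2][: config.true_n]
    while len(pts) < config.true_n:  # pragma: no cover - tiny probability
        extra = rng.uniform(-r, r, size=(config.true_n, 3))
        extra = extra[np.sum(extra ** 2, axis=1) <= r ** 2]
        pts = np.vstack([pts, extra])[: config.true_n]

    d = config.design
    t = config.cut_thickness_um
    z0 = -r - rng.uniform(0, t)                      # random section offset
    n_sections = int(np.ceil((r - z0) / t))
    sec_idx = np.floor((pts[:, 2] - z0) / t).astype(int)
    first = int(rng.integers(d.section_interval))    # which series is counted
    ox = rng.uniform(0, d.grid_x)                    # random grid offset
    oy = rng.uniform(0, d.grid_y)
    in_frame = (((pts[:, 0] - ox) % d.grid_x) < d.frame_x) \
        & (((pts[:, 1] - oy) % d.grid_y) < d.frame_y)
    counted_sections = np.arange(first, n_sections, d.section_interval)
    tallies = np.zeros(len(counted_sections), dtype=int)
    for j, s in enumerate(counted_sections):
        tallies[j] = int(np.sum((sec_idx == s) & in_frame))
    return CellFieldSample(tallies=tallies, design=d,
                           true_n=int(config.true_n),
                           n_sections=n_sections)
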