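"""Synthetic bulk omics with known cell-type-specific disease effects.

The generator mirrors a case-control design: half of the samples are cases
(X = +0.5) and half controls (X = -0.5); 5% of markers carry a disease
effect in exactly one cell type (half up-, half down-regulated, split
evenly over cell types); the per-marker baseline level mu and noise sigma
are drawn on the normalized scale; cell-type levels are sampled from
N(mu, sigma^2) (plus +/- beta in the affected cell type of cases), mapped
to the linear scale with g, and mixed with the cell-type composition to
give the bulk measurement.  Effect sizes are log methylation odds ratios
(logit scale) or log fold changes (log scale).

Composition is drawn from a Dirichlet whose concentration is moment-matched
to target mean proportions and the standard deviation of the most abundant
cell type: s = m(1-m)/SD^2 - 1, alpha_h = mean_h * s.  Default targets are
blood leukocyte panels: a 7-cell-type methylation panel (neutrophil-
dominated, CVs 0.2-0.6 except eosinophils) and a 6-cell-type expression
panel with uniformly low CV (~0.1), the regime where interaction-term
collinearity is most severe.

A second, "marker gene" scenario zeroes the linear-scale level of every
non-target cell type at differentially expressed genes, so non-target cell
types contribute no noise to the bulk signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .model import OmicsDataset
from .scales import get_scale

# blood panel targets (mean proportion, SD) used as generator defaults
METHYLATION_CELL_TYPES = ["Neu", "CD4T", "CD8T", "NK", "Mono", "Bcell", "Eos"]
METHYLATION_MEANS = np.array([0.59, 0.10, 0.08, 0.08, 0.07, 0.07, 0.01])
METHYLATION_SDS = np.array([0.11, 0.06, 0.05, 0.04, 0.02, 0.03, 0.02])

EXPRESSION_CELL_TYPES = ["Gran", "CD4T", "CD8T", "Mono", "NK", "Bcell"]
EXPRESSION_MEANS = np.array([0.53, 0.22, 0.10, 0.07, 0.05, 0.03])
EXPRESSION_SDS = np.array([0.037, 0.020, 0.013, 0.004, 0.012, 0.003])


@dataclass
class SimulationConfig:
    """Study conditions for one simulated dataset.

    ``effect_size`` is on the normalized scale (log OR for logit, log FC for
    log).  Baseline distributions supply the per-marker (mu, sigma) pairs:
    ``baseline_mean_distribution`` is either
    ``{"kind": "normal_mixture", "means": .., "sds": .., "weights": ..}``
    (bimodal, mimicking logit-scale methylation) or
    ``{"kind": "normal", "mean": .., "sd": ..}``;
    ``baseline_sd_distribution`` is ``{"kind": "uniform", "low":.., "high":..}``.
    """

    n_samples: int = 200
    n_markers: int = 1000
    cell_type_means: np.ndarray = field(
        default_factory=lambda: METHYLATION_MEANS.copy())
    cell_type_sds: np.ndarray = field(
        default_factory=lambda: METHYLATION_SDS.copy())
    cell_types: Optional[list] = None
    frac_de: float = 0.05
    effect_size: float = float(np.log(1.6))
    scale: str = "logit"
    baseline_mean_distribution: dict = field(default_factory=lambda: {
        "kind": "normal_mixture", "means": (-2.2, 2.2), "sds": (1.0, 1.0),
        "weights": (0.5, 0.5)})
    baseline_sd_distribution: dict = field(default_factory=lambda: {
        "kind": "uniform", "low": 0.1, "high": 0.5})
    scenario: str = "standard"
    seed: int = 0

    def __post_init__(self):
        self.cell_type_means = np.asarray(self.cell_type_means, dtype=float)
        self.cell_type_sds = np.asarray(self.cell_type_sds, dtype=float)
        if np.any(self.cell_type_means <= 0):
            raise ValueError("cell type mean proportions must be positive")
        if not 0.0 <= self.frac_de <= 1.0:
            raise ValueError("frac_de must be in [0, 1]")
        if not np.isfinite(self.effect_size):
            raise ValueError("effect_size must be finite")
        if self.n_samples % 2:
            raise ValueError("n_samples must be even (equal case/control split)")
        if self.scenario not in ("standard", "marker_gene"):
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if self.cell_types is None:
            self.cell_types = [f"ct{h+1}" for h in range(len(self.cell_type_means))]


def methylation_config(**overrides) -> SimulationConfig:
    """7-cell-type blood methylation panel; default effect log(OR 1.6)."""
    kw = dict(cell_type_means=METHYLATION_MEANS.copy(),
              cell_type_sds=METHYLATION_SDS.copy(),
              cell_types=list(METHYLATION_CELL_TYPES),
              scale="logit", effect_size=float(np.log(1.6)))
    kw.update(overrides)
    return SimulationConfig(**kw)


def expression_config(**overrides) -> SimulationConfig:
    """6-cell-type blood expression panel; default effect log(FC 3.0)."""
    kw = dict(cell_type_means=EXPRESSION_MEANS.copy(),
              cell_type_sds=EXPRESSION_SDS.copy(),
              cell_types=list(EXPRESSION_CELL_TYPES),
              scale="log", effect_size=float(np.log(3.0)),
              baseline_mean_distribution={"kind": "normal", "mean": 3.0,
                                          "sd": 2.0},
              baseline_sd_distribution={"kind": "uniform", "low": 0.3,
                                        "high": 1.0})
    kw.update(overrides)
    return SimulationConfig(**kw)


@dataclass
class SimulationTruth:
    """Ground truth: per-marker affected cell type/direction and the
    case-control coding (+0.5 / -0.5) per sample."""

    table: pd.DataFrame          # marker, cell_type, direction, effect_size
    case_control: np.ndarray     # (n_samples,)

    def affected(self) -> pd.DataFrame:
        return self.table[self.table["direction"] != 0]


# ---------------------------------------------------------------------------

def simulate_composition(means, sds, n_samples: int, rng) -> np.ndarray:
    """Dirichlet composition moment-matched on the most abundant cell type.

    Concentration s = m(1-m)/SD^2 - 1 where (m, SD) are the target mean and
    SD of the most abundant cell type; alpha_h = mean_h * s.  Rows are
    nonnegative and sum to one.
    """
    means = np.asarray(means, dtype=float)
    sds = np.asarray(sds, dtype=float)
    means = means / means.sum()
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    if means.size == 1:
        return np.ones((n_samples, 1))
    top = int(np.argmax(means))
    m, sd = means[top], sds[top]
    s = m * (1.0 - m) / sd**2 - 1.0
    if s <= 0:
        raise ValueError(
            f"target SD {sd} for the most abundant cell type (mean {m}) is "
            "infeasible for a Dirichlet: requires concentration <= 0")
    return rng.dirichlet(means * s, size=n_samples)


def assign_effects(n_markers: int, n_cell_types: int, frac_de: float,
                   rng, cell_types=None, effect_size=np.nan) -> pd.DataFrame:
    """Assign markers to (cell type, direction) strata.

    Exactly floor(n_markers * frac_de / (2H)) markers per stratum; the
    remainder are null.  Marker-to-stratum assignment is uniformly random.
    """
    H = n_cell_types
    if n_markers < 2 * H and frac_de > 0:
        per = 0
    else:
        per = int(np.floor(n_markers * frac_de / (2 * H)))
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    if cell_types is None:
        cell_types = [f"ct{h+1}" for h in range(H)]
    order = rng.permutation(n_markers)
    cell = np.array([None] * n_markers, dtype=object)
    direction = np.zeros(n_markers, dtype=int)
    pos = 0
    for h in cell_types:
        for sign in (+1, -1):
            idx = order[pos:pos + per]
            cell[idx] = h
            direction[idx] = sign
            pos += per
    return pd.DataFrame({
        "marker": [f"m{j:06d}" for j in range(n_markers)],
        "cell_type": cell,
        "direction": direction,
        "effect_size": np.where(direction != 0, effect_size, 0.0),
    })


def _draw_baselines(config: SimulationConfig, rng):
    spec = config.baseline_mean_distribution
    m = config.n_markers
    if spec["kind"] == "normal":
        mu = rng.normal(spec["mean"], spec["sd"], size=m)
    elif spec["kind"] == "normal_mixture":
        means = np.asarray(spec["means"], dtype=float)
        sds = np.asarray(spec["sds"], dtype=float)
        w = np.asarray(spec["weights"], dtype=float)
        comp = rng.choice(len(means), size=m, p=w / w.sum())
        mu = rng.normal(means[comp], sds[comp])
    else:
        raise ValueError(f"unknown baseline mean distribution {spec['kind']!r}")
    sspec = config.baseline_sd_distribution
    if sspec["kind"] != "uniform":
        raise ValueError(f"unknown baseline sd distribution {sspec['kind']!r}")
    sd = rng.uniform(sspec["low"], sspec["high"], size=m)
    return mu, sd


def simulate_bulk(config: SimulationConfig):
    """Generate one dataset: returns (OmicsDataset, SimulationTruth).

    A pure function of the config (seed included).
    """
    rng = np.random.default_rng(config.seed)
    n, H = config.n_samples, len(config.cell_type_means)
    scale = get_scale(config.scale)
    marker_gene = config.scenario == "marker_gene"

    W = simulate_composition(config.cell_type_means, config.cell_type_sds,
                             n, rng)
    # exact half case / half control split
    x = np.full(n, -0.5)
    x[rng.permutation(n)[:n // 2]] = 0.5

    truth = assign_effects(config.n_markers, H, config.frac_de, rng,
                           cell_types=config.cell_types,
                           effect_size=config.effect_size)
    mu0, sd0 = _draw_baselines(config, rng)
    target = np.full(config.n_markers, -1)
    for h_idx, h in enumerate(config.cell_types):
        target[(truth["cell_type"] == h).to_numpy()] = h_idx
    direction = truth["direction"].to_numpy()

    case = x > 0
    Y = np.empty((config.n_markers, n))
    chunk = max(1, int(4_000_000 // (n * H)))
    for start in range(0, config.n_markers, chunk):
        stop = min(start + chunk, config.n_markers)
        b = stop - start
        levels = (mu0[start:stop, None, None]
                  + sd0[start:stop, None, None] * rng.normal(size=(b, n, H)))
        de = target[start:stop] >= 0
        if np.any(de):
            jj = np.where(de)[0]
            levels[jj[:, None], np.where(case)[0][None, :], target[start:stop][jj][:, None]] += (
                direction[start:stop][jj][:, None] * config.effect_size)
        lin = scale.g(levels)
        if marker_gene and np.any(de):
            # non-target cell types contribute exactly zero at DE markers
            mask = np.zeros((b, H), dtype=bool)
            mask[np.where(de)[0], target[start:stop][de]] = True
            lin = np.where(de[:, None, None], lin * mask[:, None, :], lin)
        Y[start:stop] = np.einsum("bnh,nh->bn", lin, W)

    data = OmicsDataset(
        Y=Y, W=W, X=x[:, None], C=np.zeros((n, 0)),
        markers=list(truth["marker"]),
        samples=[f"s{i:04d}" for i in range(n)],
        cell_types=list(config.cell_types),
        traits=["disease"], covariates=[],
    )
    return data, SimulationTruth(table=truth, case_control=x)


def simulate_marker_gene_bulk(config: SimulationConfig):
    """Marker-gene scenario (log scale): at DE genes all non-target cell
    types have zero linear-scale expression for cases and controls alike."""
    from dataclasses import replace
    return simulate_bulk(replace(config, scenario="marker_gene"))
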