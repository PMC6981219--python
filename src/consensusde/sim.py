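"""Negative-binomial count simulator with planted effects, plus truth-aware
evaluation.

The generator emulates the structure two-group bulk RNA-seq pipelines
assume: gene-wise NB counts whose dispersion follows a decreasing
``phi(mu) = a / mu + b`` mean-dispersion trend, heterogeneous library
depths, a configurable fraction of genes with planted symmetric log2 fold
changes bounded away from zero, and optional hidden unwanted-variation
factors acting multiplicatively on the log scale. Everything derives from
one integer seed; there are no unseeded draws.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .data import CountMatrix, StudyDesign
from .errors import ConfigError, IdentifierError, StructuralError

__all__ = [
    "SimConfig",
    "SimTruth",
    "simulate_dataset",
    "simulate_null",
    "evaluate_calls",
    "recovery_report",
]


@dataclass
class SimConfig:
    """Parameters of the synthetic two-group RNA-seq dataset.

    Defaults mirror a realistic bulk experiment: six replicates per group,
    a genome-scale gene panel, log-normal baseline expression spanning
    several orders of magnitude, dispersions decreasing with mean
    (``phi = a / mu + b``), and ~35% spread in sequencing depth.
    """

    n_genes: int = 15000
    n_per_group: int = 6
    baseline_meanlog: float = 4.0   # log-scale mean of baseline expression
    baseline_sdlog: float = 1.5
    disp_a: float = 3.0             # phi(mu) = disp_a / mu + disp_b
    disp_b: float = 0.1
    frac_de: float = 0.0
    lfc_magnitude: float = 1.0      # |log2 FC| location for planted genes
    lfc_jitter_sd: float = 0.25
    lfc_min: float = 0.5            # planted effects bounded away from 0
    libsize_sdlog: float = 0.3
    n_unwanted_factors: int = 0
    unwanted_effect_sd: float = 0.5
    length_meanlog: float = 7.3     # collapsed gene length ~ exp(7.3) = 1.5 kb
    length_sdlog: float = 0.5
    condition_labels: tuple[str, str] = ("control", "treatment")
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.frac_de <= 1.0):
            raise ConfigError(f"frac_de must be in [0, 1], got {self.frac_de}")
        if self.n_genes < 1 or self.n_per_group < 2:
            raise ConfigError("need n_genes >= 1 and n_per_group >= 2")
        for name in ("baseline_sdlog", "lfc_magnitude", "lfc_min"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        for name in ("disp_a", "disp_b", "lfc_jitter_sd", "libsize_sdlog", "unwanted_effect_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be nonnegative")
        if self.n_unwanted_factors < 0:
            raise ConfigError("n_unwanted_factors must be nonnegative")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["condition_labels"] = list(self.condition_labels)
        return d


@dataclass
class SimTruth:
    """Planted ground truth paired with one simulated dataset."""

    gene_ids: list[str]
    is_de: np.ndarray
    true_log2fc: np.ndarray
    baseline_mean: np.ndarray
    dispersion: np.ndarray
    depth_factors: np.ndarray
    unwanted_scores: np.ndarray  # samples x n_unwanted_factors
    config: SimConfig

    @property
    def n_de(self) -> int:
        return int(self.is_de.sum())

    @property
    def de_genes(self) -> set[str]:
        return {g for g, flag in zip(self.gene_ids, self.is_de) if flag}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": self.gene_ids,
                "is_de": self.is_de.astype(int),
                "true_log2fc": self.true_log2fc,
                "baseline_mean": self.baseline_mean,
                "dispersion": self.dispersion,
            }
        )


def simulate_dataset(config: SimConfig) -> tuple[CountMatrix, StudyDesign, SimTruth]:
    """Draw one two-group NB dataset with planted effects.

    ``counts[g, j] ~ NB(mean = mu_g * 2**(x_j * lfc_g) * depth_j *
    exp(unwanted), dispersion = phi_g)`` with ``x_j`` the 0/1 group
    indicator, sampled as a gamma-Poisson mixture. Fully reproducible from
    ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    g, n = config.n_genes, 2 * config.n_per_group

    mu = rng.lognormal(config.baseline_meanlog, config.baseline_sdlog, g)
    phi = config.disp_a / mu + config.disp_b

    n_de = int(round(config.frac_de * g))
    de_idx = rng.choice(g, size=n_de, replace=False)
    is_de = np.zeros(g, dtype=bool)
    is_de[de_idx] = True
    magnitudes = np.maximum(
        config.lfc_min,
        config.lfc_magnitude + rng.normal(0.0, config.lfc_jitter_sd, n_de),
    )
    signs = rng.choice([-1.0, 1.0], size=n_de)
    lfc = np.zeros(g)
    lfc[de_idx] = signs * magnitudes

    depth = rng.lognormal(0.0, config.libsize_sdlog, n)
    depth /= np.exp(np.mean(np.log(depth)))

    k = config.n_unwanted_factors
    scores = rng.normal(0.0, 1.0, size=(n, k)) if k else np.zeros((n, 0))
    loadings = rng.normal(0.0, config.unwanted_effect_sd, size=(g, k)) if k else np.zeros((g, 0))

    x = np.repeat([0.0, 1.0], config.n_per_group)  # control block, then treatment
    mean = (
        mu[:, None]
        * 2.0 ** (lfc[:, None] * x[None, :])
        * depth[None, :]
        * np.exp(loadings @ scores.T)
    )

    poisson_like = phi < 1e-12
    counts = np.empty((g, n), dtype=np.int64)
    if np.any(poisson_like):
        counts[poisson_like] = rng.poisson(mean[poisson_like])
    if np.any(~poisson_like):
        shape = (1.0 / phi[~poisson_like])[:, None]
        scale = phi[~poisson_like][:, None] * mean[~poisson_like]
        counts[~poisson_like] = rng.poisson(rng.gamma(shape, scale))

    lengths = np.maximum(
        200, np.rint(rng.lognormal(config.length_meanlog, config.length_sdlog, g))
    ).astype(np.int64)

    gene_ids = [f"gene_{i:05d}" for i in range(g)]
    ctrl, treat = config.condition_labels
    sample_ids = [f"{ctrl}_{i + 1}" for i in range(config.n_per_group)] + [
        f"{treat}_{i + 1}" for i in range(config.n_per_group)
    ]
    cm = CountMatrix(
        gene_ids=gene_ids, sample_ids=sample_ids, counts=counts, gene_lengths_bp=lengths
    )
    design = StudyDesign(
        sample_ids=sample_ids,
        condition=[ctrl] * config.n_per_group + [treat] * config.n_per_group,
    )
    truth = SimTruth(
        gene_ids=gene_ids,
        is_de=is_de,
        true_log2fc=lfc,
        baseline_mean=mu,
        dispersion=phi,
        depth_factors=depth,
        unwanted_scores=scores,
        config=config,
    )
    return cm, design, truth


def simulate_null(config: SimConfig) -> tuple[CountMatrix, StudyDesign, SimTruth]:
    """Simulate with no planted effects; rejects configs with ``frac_de != 0``."""
    if config.frac_de != 0:
        raise ConfigError(f"simulate_null requires frac_de = 0, got {config.frac_de}")
    return simulate_dataset(config)


def evaluate_calls(calls: Iterable[str], truth: SimTruth) -> dict:
    """Confusion counts and rates of a call set against the planted truth.

    ``empirical_FDR = FP / max(1, FP + TP)`` (0 when nothing is called);
    ``power = TP / n_de`` (0 when nothing was planted).
    """
    call_set = set(calls)
    universe = set(truth.gene_ids)
    unknown = call_set - universe
    if unknown:
        raise IdentifierError(f"called gene {sorted(unknown)[0]!r} not in the truth universe")
    de = truth.de_genes
    tp = len(call_set & de)
    fp = len(call_set - de)
    fn = len(de - call_set)
    tn = len(universe) - tp - fp - fn
    return {
        "TP": tp,
        "FP": fp,
        "FN": fn,
        "TN": tn,
        "empirical_FDR": fp / max(1, fp + tp),
        "power": tp / truth.n_de if truth.n_de else 0.0,
    }


def recovery_report(grid, truth: SimTruth, min_true_mean: float = 20.0) -> pd.DataFrame:
    """Per-model and consensus effect recovery against planted truth.

    Fold-change bias and RMSE are computed over planted genes with true
    baseline mean at least ``min_true_mean`` counts, using each model's
    median log2 fold change across its normalizations (the consensus row
    uses the median across all cells). FDR and power evaluate each model's
    mean-q target set and the final consensus set.
    """
    from .consensus import call_consensus, mean_q_aggregate

    if list(grid.gene_ids) != list(truth.gene_ids):
        raise StructuralError("grid and truth cover different gene universes")
    mean_q = mean_q_aggregate(grid)
    calls = call_consensus(grid, threshold=grid.threshold, k_required=grid.k_required)

    sel = truth.is_de & (truth.baseline_mean >= min_true_mean)
    rows = []
    for model in grid.models:
        lfc_cells = np.vstack(
            [grid.cells[(norm, model)].log2_fold_change for norm in grid.normalizations]
        )
        lfc_est = np.median(lfc_cells, axis=0)
        err = lfc_est[sel] - truth.true_log2fc[sel]
        target = {g for g, q in zip(grid.gene_ids, mean_q[model]) if q < grid.threshold}
        ev = evaluate_calls(target, truth)
        rows.append(
            {
                "method": model,
                "lfc_bias": float(np.mean(err)) if err.size else np.nan,
                "lfc_rmse": float(np.sqrt(np.mean(err**2))) if err.size else np.nan,
                "empirical_FDR": ev["empirical_FDR"],
                "power": ev["power"],
                "n_called": ev["TP"] + ev["FP"],
            }
        )
    all_lfc = np.vstack([res.log2_fold_change for res in grid.cells.values()])
    lfc_est = np.median(all_lfc, axis=0)
    err = lfc_est[sel] - truth.true_log2fc[sel]
    deg_set = set(calls.loc[calls["is_deg"], "gene_id"])
    ev = evaluate_calls(deg_set, truth)
    rows.append(
        {
            "method": "consensus",
            "lfc_bias": float(np.mean(err)) if err.size else np.nan,
            "lfc_rmse": float(np.sqrt(np.mean(err**2))) if err.size else np.nan,
            "empirical_FDR": ev["empirical_FDR"],
            "power": ev["power"],
            "n_called": ev["TP"] + ev["FP"],
        }
    )
    return pd.DataFrame(rows)
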