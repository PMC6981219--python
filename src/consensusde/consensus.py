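"""The normalization x model grid, mean-q aggregation, and consensus calls.

The grid runs every registered normalization against every registered
model over one shared gene universe. Within each cell, p-values are BH
adjusted; per model, q-values are then averaged across normalizations,
and a gene is a *target* of that model when its mean q falls strictly
below the threshold (default 0.25). The final consensus call requires the
gene to be a target of at least ``k_required`` models (default: all five),
with direction taken as the sign of the median fold change across all
cells.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import CountMatrix, DEResult, StudyDesign
from .de import MODELS, fit_dispersion
from .errors import StructuralError
from .normalize import NORMALIZATIONS, NormalizationResult

__all__ = [
    "ConsensusGrid",
    "run_grid",
    "mean_q_aggregate",
    "call_consensus",
    "classify_volcano",
    "compare_deg_sets",
]

DEFAULT_THRESHOLD = 0.25
NB_MODELS = {"nb_wald", "nb_lrt_robust"}


@dataclass
class ConsensusGrid:
    """All grid cells plus aggregation state."""

    gene_ids: list[str]
    normalizations: list[str]
    models: list[str]
    cells: dict[tuple[str, str], DEResult]
    threshold: float = DEFAULT_THRESHOLD
    k_required: int | None = None
    cell_messages: dict[tuple[str, str], list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.k_required is None:
            self.k_required = len(self.models)
        for norm in self.normalizations:
            for model in self.models:
                if (norm, model) not in self.cells:
                    raise StructuralError(f"grid is missing cell ({norm}, {model})")

    @property
    def n_cells(self) -> int:
        return len(self.cells)


@dataclass
class _CellInputs:
    counts: np.ndarray
    offsets: np.ndarray | None
    effective_depths: np.ndarray | None
    values: np.ndarray
    messages: list[str]


def _prepare_inputs(cm: CountMatrix, norm: NormalizationResult) -> _CellInputs:
    """Adapt one normalization's output to what each model family consumes.

    Factor methods: raw counts plus log-depth offsets for the count models,
    factor-divided counts for the rank/t tests. Matrix methods: the
    normalized matrix rounded to integers (with a recorded caveat) for the
    count models, the matrix itself for the rank/t tests.
    """
    if not norm.is_matrix:
        values = cm.counts / norm.size_factors[None, :]
        return _CellInputs(
            counts=cm.counts,
            offsets=norm.offsets,
            effective_depths=norm.effective_depths,
            values=values,
            messages=list(norm.messages),
        )
    rounded = np.rint(norm.normalized).astype(np.int64)
    depths = np.maximum(rounded.sum(axis=0), 1).astype(float)
    msg = (
        f"{norm.method}: normalized matrix rounded to integers for count models "
        "(variance model approximate)"
    )
    return _CellInputs(
        counts=rounded,
        offsets=None,
        effective_depths=depths,
        values=norm.normalized,
        messages=list(norm.messages) + [msg],
    )


def run_grid(
    cm: CountMatrix,
    design: StudyDesign,
    normalizations: list[str] | None = None,
    models: list[str] | None = None,
    threshold: float = DEFAULT_THRESHOLD,
    k_required: int | None = None,
) -> ConsensusGrid:
    """Populate every (normalization, model) cell over one gene universe.

    Any cell failure aborts the whole run with the failing cell named; no
    partial grids are returned silently.
    """
    normalizations = list(NORMALIZATIONS) if normalizations is None else list(normalizations)
    models = list(MODELS) if models is None else list(models)
    if not normalizations or not models:
        raise ValueError("need at least one normalization and one model")
    unknown_n = [n for n in normalizations if n not in NORMALIZATIONS]
    unknown_m = [m for m in models if m not in MODELS]
    if unknown_n:
        raise ValueError(f"unknown normalization {unknown_n[0]!r}")
    if unknown_m:
        raise ValueError(f"unknown model {unknown_m[0]!r}")
    design = design.aligned_to(cm)

    cells: dict[tuple[str, str], DEResult] = {}
    cell_messages: dict[tuple[str, str], list[str]] = {}
    needs_dispersion = bool(NB_MODELS & set(models))
    for norm_name in normalizations:
        try:
            norm = NORMALIZATIONS[norm_name](cm, design)
            inputs = _prepare_inputs(cm, norm)
            dispersion = None
            if needs_dispersion:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    dispersion = fit_dispersion(inputs.counts, inputs.offsets, design)
        except Exception as exc:  # noqa: BLE001 - re-raised with the cell named
            raise StructuralError(f"normalization {norm_name!r} failed: {exc}") from exc
        for model_name in models:
            try:
                result = MODELS[model_name](
                    inputs.counts,
                    design,
                    offsets=inputs.offsets,
                    effective_depths=inputs.effective_depths,
                    values=inputs.values,
                    dispersion=dispersion,
                    normalization=norm_name,
                )
            except Exception as exc:  # noqa: BLE001
                raise StructuralError(
                    f"grid cell ({norm_name}, {model_name}) failed: {exc}"
                ) from exc
            result.gene_ids = list(cm.gene_ids)
            cells[(norm_name, model_name)] = result
            cell_messages[(norm_name, model_name)] = list(inputs.messages)

    return ConsensusGrid(
        gene_ids=list(cm.gene_ids),
        normalizations=normalizations,
        models=models,
        cells=cells,
        threshold=threshold,
        k_required=k_required if k_required is not None else len(models),
        cell_messages=cell_messages,
    )


def mean_q_aggregate(grid: ConsensusGrid) -> dict[str, np.ndarray]:
    """Per model, the arithmetic mean of q-values across its normalizations."""
    out: dict[str, np.ndarray] = {}
    for model in grid.models:
        qs = []
        for norm in grid.normalizations:
            if (norm, model) not in grid.cells:
                raise StructuralError(f"grid is missing cell ({norm}, {model})")
            qs.append(grid.cells[(norm, model)].q_value)
        out[model] = np.mean(np.vstack(qs), axis=0)
    return out


def call_consensus(
    grid: ConsensusGrid,
    threshold: float | None = None,
    k_required: int | None = None,
) -> pd.DataFrame:
    """Apply the mean-q rule and the k-of-M consensus.

    A gene is a target of a model when its mean q is *strictly* below
    ``threshold``; it is a consensus DEG when it is a target of at least
    ``k_required`` models. Direction is the sign of the median log2 fold
    change across all cells ("ambiguous" at exactly zero).
    """
    threshold = grid.threshold if threshold is None else threshold
    k_required = grid.k_required if k_required is None else k_required
    if k_required > len(grid.models):
        raise ValueError(
            f"k_required={k_required} exceeds the {len(grid.models)} registered models"
        )
    grid.threshold = threshold
    grid.k_required = k_required

    mean_q = mean_q_aggregate(grid)
    n_genes = len(grid.gene_ids)
    n_detected = np.zeros(n_genes, dtype=int)
    for model in grid.models:
        n_detected += (mean_q[model] < threshold).astype(int)
    is_deg = n_detected >= k_required

    all_lfc = np.vstack([res.log2_fold_change for res in grid.cells.values()])
    median_lfc = np.median(all_lfc, axis=0)
    direction = np.where(median_lfc > 0, "up", np.where(median_lfc < 0, "down", "ambiguous"))

    data = {"gene_id": grid.gene_ids}
    for model in grid.models:
        data[f"mean_q_{model}"] = mean_q[model]
    data["n_models_detected"] = n_detected
    data["median_log2FC"] = median_lfc
    data["direction"] = direction
    data["is_deg"] = is_deg
    return pd.DataFrame(data)


def classify_volcano(cell: DEResult, q_cutoff: float = 0.01) -> pd.DataFrame:
    """Plot-ready volcano table: gene, lfc, -log10 q, and up/down/ns label."""
    q = cell.q_value
    lfc = cell.log2_fold_change
    label = np.where(
        (q < q_cutoff) & (lfc > 0), "up", np.where((q < q_cutoff) & (lfc < 0), "down", "ns")
    )
    with np.errstate(divide="ignore"):
        neg_log10_q = -np.log10(np.clip(q, 1e-300, None))
    return pd.DataFrame(
        {
            "gene_id": cell.gene_ids,
            "log2FC": lfc,
            "neg_log10_q": neg_log10_q,
            "label": label,
        }
    )


def compare_deg_sets(set_a, set_b) -> dict:
    """Overlap summary of two DEG sets (e.g. two abstinence timepoints)."""
    a, b = set(set_a), set(set_b)
    return {
        "a_only": len(a - b),
        "b_only": len(b - a),
        "intersection": len(a & b),
        "a_only_genes": sorted(a - b),
        "b_only_genes": sorted(b - a),
        "intersection_genes": sorted(a & b),
    }
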