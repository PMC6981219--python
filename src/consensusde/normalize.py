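"""Count-level normalization methods for the grid.

Two families of result are produced:

* **factor methods** (TMM, UQ, Median, PoissonSeq) return per-sample
  *relative depth* factors with geometric mean 1 — multiplying one sample's
  counts by ``c`` multiplies its pre-rescaling factor by ``c``. Effective
  depth is ``factor x geometric-mean library size`` and its natural log is
  the offset handed to count models.
* **matrix methods** (TMM_CPM, RPKM, FullQuantile, RUV) return a transformed
  gene x sample expression matrix.

All methods are deterministic; the registry :data:`NORMALIZATIONS` maps the
grid tags to callables of signature ``(counts, design) -> NormalizationResult``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import stats

from .data import CountMatrix, StudyDesign
from .errors import AnnotationError, StructuralError

__all__ = [
    "NormalizationResult",
    "tmm_factors",
    "cpm_transform",
    "rpkm_transform",
    "uq_factors",
    "median_factors",
    "full_quantile_transform",
    "poissonseq_factors",
    "ruv_transform",
    "NORMALIZATIONS",
    "register_normalization",
]

PSEUDOCOUNT = 0.5  # continuity correction for every log transform in the package


@dataclass
class NormalizationResult:
    """Output of one normalization method.

    At least one of ``size_factors`` / ``normalized`` is present.
    ``size_factors`` are strictly positive relative depth factors with
    geometric mean 1. ``offsets`` are per-sample natural-log effective
    depths for count models (sample-level: none of the implemented methods
    produces gene-specific offsets).
    """

    method: str
    size_factors: np.ndarray | None = None
    normalized: np.ndarray | None = None
    offsets: np.ndarray | None = None
    effective_depths: np.ndarray | None = None
    params: dict = field(default_factory=dict)
    messages: list[str] = field(default_factory=list)
    converged: bool = True

    def __post_init__(self) -> None:
        if self.size_factors is None and self.normalized is None:
            raise StructuralError("normalization produced neither factors nor a matrix")
        if self.size_factors is not None:
            f = np.asarray(self.size_factors, dtype=float)
            if np.any(f <= 0) or np.any(~np.isfinite(f)):
                raise ValueError(f"{self.method}: size factors must be strictly positive")
            self.size_factors = f

    @property
    def is_matrix(self) -> bool:
        """True when the method's defining output is a transformed matrix."""
        return self.size_factors is None


def _geomean(x: np.ndarray) -> float:
    return float(np.exp(np.mean(np.log(x))))


def _rescale(factors: np.ndarray) -> np.ndarray:
    """Rescale strictly positive factors to geometric mean 1."""
    return factors / _geomean(factors)


def _check_library_sizes(cm: CountMatrix) -> np.ndarray:
    lib = cm.library_sizes.astype(float)
    if np.any(lib <= 0):
        bad = cm.sample_ids[int(np.argmax(lib <= 0))]
        raise ValueError(f"sample {bad!r} has zero total count")
    return lib


def _factor_result(method: str, cm: CountMatrix, pre_factors: np.ndarray,
                   params: dict, messages: list[str] | None = None,
                   converged: bool = True) -> NormalizationResult:
    lib = cm.library_sizes.astype(float)
    size_factors = _rescale(np.asarray(pre_factors, dtype=float))
    effective = size_factors * _geomean(lib)
    return NormalizationResult(
        method=method,
        size_factors=size_factors,
        effective_depths=effective,
        offsets=np.log(effective),
        params=params,
        messages=messages or [],
        converged=converged,
    )


# ---------------------------------------------------------------------------
# TMM
# ---------------------------------------------------------------------------


def _trim_keep(values: np.ndarray, trim: float) -> np.ndarray:
    """Boolean mask keeping the central ``1 - 2*trim`` mass by rank."""
    n = len(values)
    lo = int(np.floor(n * trim))
    hi = n - lo
    ranks = np.argsort(np.argsort(values, kind="stable"), kind="stable")
    return (ranks >= lo) & (ranks < hi)


def tmm_factors(cm: CountMatrix, trim_M: float = 0.30, trim_A: float = 0.05) -> NormalizationResult:
    """Trimmed-mean-of-M-values depth factors.

    Per sample, the log2 ratios (M) of depth-normalized counts to a reference
    sample are doubly trimmed — the central ``1 - 2*trim_M`` of M and the
    central ``1 - 2*trim_A`` of average log intensity (A) — and averaged with
    inverse asymptotic-variance weights. The composition estimate times the
    library-size ratio gives the relative depth factor; factors are rescaled
    to geometric mean 1.

    The reference is the sample whose upper quartile of depth-normalized
    counts is closest to the mean upper quartile across samples.
    """
    if cm.n_samples < 2:
        raise ValueError("TMM requires at least two samples")
    lib = _check_library_sizes(cm)
    y = cm.counts.astype(float)
    p = y / lib  # relative abundances
    uq = np.percentile(p, 75, axis=0)
    ref = int(np.argmin(np.abs(uq - uq.mean())))

    messages: list[str] = []
    comp = np.ones(cm.n_samples)
    for j in range(cm.n_samples):
        if j == ref:
            continue
        ok = (y[:, j] > 0) & (y[:, ref] > 0)
        if not np.any(ok):
            messages.append(f"sample {cm.sample_ids[j]!r}: no genes shared with reference; factor 1")
            warnings.warn(messages[-1])
            continue
        M = np.log2(p[ok, j] / p[ok, ref])
        A = 0.5 * np.log2(p[ok, j] * p[ok, ref])
        # delta-method (Poisson) variance of M on the relative-abundance
        # scale: scale-free, so rescaling a sample's counts leaves every
        # gene's weight ratio -- and hence the trimmed mean -- unchanged
        v = 1.0 / p[ok, j] + 1.0 / p[ok, ref]
        keep = _trim_keep(M, trim_M) & _trim_keep(A, trim_A)
        if not np.any(keep) or np.all(v[keep] <= 0):
            messages.append(
                f"sample {cm.sample_ids[j]!r}: all genes trimmed; fallback factor 1"
            )
            warnings.warn(messages[-1])
            continue
        w = 1.0 / v[keep]
        comp[j] = 2.0 ** (np.sum(w * M[keep]) / np.sum(w))

    pre = comp * lib
    return _factor_result(
        "TMM", cm, pre,
        params={"trim_M": trim_M, "trim_A": trim_A, "reference_sample": cm.sample_ids[ref]},
        messages=messages,
    )


def cpm_transform(cm: CountMatrix, factors: Sequence[float] | np.ndarray | None = None) -> NormalizationResult:
    """Counts per million on ``library size x factor`` effective depths."""
    lib = cm.library_sizes.astype(float)
    f = np.ones(cm.n_samples) if factors is None else np.asarray(factors, dtype=float)
    depth = lib * f
    if np.any(depth <= 0) or np.any(~np.isfinite(depth)):
        bad = cm.sample_ids[int(np.argmax((depth <= 0) | ~np.isfinite(depth)))]
        raise ValueError(f"sample {bad!r} has non-positive effective depth")
    normalized = cm.counts / depth * 1e6
    return NormalizationResult(method="CPM", normalized=normalized, params={"factors": f.tolist()})


def tmm_cpm_transform(cm: CountMatrix, trim_M: float = 0.30, trim_A: float = 0.05) -> NormalizationResult:
    """CPM on TMM effective depths (the grid's ``TMM_CPM`` method)."""
    tmm = tmm_factors(cm, trim_M=trim_M, trim_A=trim_A)
    lib = cm.library_sizes.astype(float)
    # depth factors already contain library size; convert to composition
    # factors so counts / (libsize x factor) uses the TMM effective depth
    res = cpm_transform(cm, factors=tmm.effective_depths / lib)
    return NormalizationResult(
        method="TMM_CPM",
        normalized=res.normalized,
        params=tmm.params,
        messages=tmm.messages,
    )


def rpkm_transform(cm: CountMatrix) -> NormalizationResult:
    """Reads per kilobase of collapsed gene model per million mapped reads."""
    if cm.gene_lengths_bp is None:
        raise AnnotationError("RPKM requires gene lengths (gene_lengths_bp missing)")
    lib = _check_library_sizes(cm)
    length_kb = cm.gene_lengths_bp / 1e3
    normalized = cm.counts / (length_kb[:, None] * (lib / 1e6)[None, :])
    return NormalizationResult(method="RPKM", normalized=normalized)


# ---------------------------------------------------------------------------
# quantile-based factors
# ---------------------------------------------------------------------------


def uq_factors(cm: CountMatrix) -> NormalizationResult:
    """Upper-quartile depth factors.

    Per-sample factor proportional to the 75th percentile of the sample's
    nonzero counts (linear-interpolation percentile, index ``0.75 (n-1)``),
    rescaled to geometric mean 1.
    """
    _check_library_sizes(cm)
    pre = np.empty(cm.n_samples)
    for j in range(cm.n_samples):
        nz = cm.counts[cm.counts[:, j] > 0, j]
        if nz.size < 4:
            raise ValueError(
                f"sample {cm.sample_ids[j]!r} has {nz.size} nonzero genes; upper quartile needs >= 4"
            )
        pre[j] = np.percentile(nz, 75)
    return _factor_result("UQ", cm, pre, params={})


def median_factors(cm: CountMatrix) -> NormalizationResult:
    """Depth factors proportional to the median of each sample's nonzero counts."""
    _check_library_sizes(cm)
    pre = np.empty(cm.n_samples)
    for j in range(cm.n_samples):
        nz = cm.counts[cm.counts[:, j] > 0, j]
        if nz.size < 1:
            raise ValueError(f"sample {cm.sample_ids[j]!r} has no nonzero counts")
        pre[j] = np.median(nz)
    return _factor_result("Median", cm, pre, params={})


def full_quantile_transform(cm: CountMatrix) -> NormalizationResult:
    """Full-quantile normalization.

    Every sample's values are replaced rank-wise by the mean of the sorted
    columns, so afterwards each column is an exact permutation of one common
    reference vector. Ties within a column are broken by input order
    (stable), which keeps the output multiset identical across samples and
    makes the transform exactly idempotent.
    """
    if cm.n_samples < 2:
        raise ValueError("full-quantile normalization requires at least two samples")
    return NormalizationResult(
        method="FullQuantile", normalized=full_quantile_array(cm.counts.astype(float))
    )


def full_quantile_array(values: np.ndarray) -> np.ndarray:
    """Rank-wise substitution by the mean of sorted columns (any real matrix)."""
    y = np.asarray(values, dtype=float)
    ref = np.sort(y, axis=0).mean(axis=1)
    out = np.empty_like(y)
    for j in range(y.shape[1]):
        order = np.argsort(y[:, j], kind="stable")
        out[order, j] = ref
    return out


# ---------------------------------------------------------------------------
# PoissonSeq-style iterative depth estimation
# ---------------------------------------------------------------------------


def poissonseq_factors(
    cm: CountMatrix,
    design: StudyDesign | None = None,
    tol: float = 1e-8,
    max_iter: int = 20,
) -> NormalizationResult:
    """Iterative depth estimation from a Poisson goodness-of-fit null set.

    Starting from library-size depths, each iteration scores every gene by a
    Poisson goodness-of-fit statistic against expected counts from the
    current depths alone (one mean per gene — genes with a real condition
    effect fit this depth-only model badly and score high), keeps the
    least-variable half as the putative null set, and re-estimates each
    sample's depth as its share of the null-set counts. Stops when depths
    change by less than ``tol`` or after ``max_iter`` iterations
    (non-convergence is flagged, not fatal). ``design`` is accepted for
    interface uniformity; the depth-only score does not use it.
    """
    del design
    lib = _check_library_sizes(cm)
    y = cm.counts.astype(float)
    expressed = y.sum(axis=1) > 0

    depth = lib / lib.sum()
    converged = False
    for _ in range(max_iter):
        totals = y.sum(axis=1)
        expected = totals[:, None] * depth[None, :]
        with np.errstate(divide="ignore", invalid="ignore"):
            contrib = np.where(expected > 0, (y - expected) ** 2 / expected, 0.0)
        gof = contrib.sum(axis=1)
        scores = gof[expressed]
        cutoff = np.median(scores)
        null_set = np.zeros(cm.n_genes, dtype=bool)
        null_set[expressed] = scores <= cutoff
        total = y[null_set].sum()
        new_depth = y[null_set].sum(axis=0) / total
        if np.max(np.abs(new_depth - depth)) < tol:
            depth = new_depth
            converged = True
            break
        depth = new_depth

    messages = [] if converged else ["PoissonSeq depth estimation did not converge; using last iterate"]
    if not converged:
        warnings.warn(messages[0])
    return _factor_result(
        "PoissonSeq", cm, depth,
        params={"tol": tol, "max_iter": max_iter},
        messages=messages, converged=converged,
    )


# ---------------------------------------------------------------------------
# RUV-style factor removal
# ---------------------------------------------------------------------------


def ruv_transform(
    cm: CountMatrix,
    design: StudyDesign,
    k: int = 1,
    control_genes: Sequence[str] | str = "empirical",
) -> NormalizationResult:
    """Remove ``k`` unwanted-variation factors estimated from control genes.

    On the ``log(count + 0.5)`` scale, condition means are removed per gene,
    the top ``k`` right singular vectors of the control-gene residual matrix
    are taken as unwanted factors, every gene's residuals are regressed on
    them, and the fitted unwanted component is subtracted. The adjusted
    matrix is returned on the linear scale, clipped at zero.

    ``control_genes="empirical"`` uses the half of genes with the largest
    first-pass Welch-t p-values as negative controls.
    """
    if k <= 0:
        raise ValueError(f"k must be a positive integer, got {k}")
    if k >= cm.n_samples - 2:
        raise ValueError(f"k={k} too large for {cm.n_samples} samples (need k < n_samples - 2)")
    design = design.aligned_to(cm)
    log_y = np.log(cm.counts + PSEUDOCOUNT)

    c_mask, t_mask = design.control_mask, design.treatment_mask
    centered = log_y.copy()
    centered[:, c_mask] -= log_y[:, c_mask].mean(axis=1, keepdims=True)
    centered[:, t_mask] -= log_y[:, t_mask].mean(axis=1, keepdims=True)

    if isinstance(control_genes, str):
        if control_genes != "empirical":
            raise ValueError(f"unknown control gene rule {control_genes!r}")
        with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore")
            t_res = stats.ttest_ind(log_y[:, t_mask], log_y[:, c_mask], axis=1, equal_var=False)
        pvals = np.where(np.isfinite(t_res.pvalue), t_res.pvalue, 1.0)
        n_ctrl = cm.n_genes // 2
        # largest p-values = least evidence of condition effect
        ctrl_idx = np.argsort(-pvals, kind="stable")[:n_ctrl]
    else:
        wanted = set(control_genes)
        ctrl_idx = np.array([i for i, g in enumerate(cm.gene_ids) if g in wanted], dtype=int)
        unknown = wanted - set(cm.gene_ids)
        if unknown:
            raise ValueError(f"control gene {sorted(unknown)[0]!r} not in count matrix")
    if len(ctrl_idx) < k + 1:
        raise ValueError(f"{len(ctrl_idx)} control genes insufficient for k={k} factors")

    _, _, vt = np.linalg.svd(centered[ctrl_idx], full_matrices=False)
    w = vt[:k].T  # samples x k, orthonormal columns
    alpha = centered @ w
    adjusted_log = log_y - alpha @ w.T
    normalized = np.clip(np.exp(adjusted_log) - PSEUDOCOUNT, 0.0, None)
    return NormalizationResult(
        method="RUV",
        normalized=normalized,
        params={
            "k": k,
            "factors": w,
            "n_control_genes": int(len(ctrl_idx)),
            "control_rule": control_genes if isinstance(control_genes, str) else "explicit",
        },
    )


# ---------------------------------------------------------------------------
# registry
# ---------------------------------------------------------------------------

NormalizationFn = Callable[[CountMatrix, StudyDesign], NormalizationResult]

NORMALIZATIONS: dict[str, NormalizationFn] = {
    "TMM": lambda cm, design: tmm_factors(cm),
    "TMM_CPM": lambda cm, design: tmm_cpm_transform(cm),
    "RPKM": lambda cm, design: rpkm_transform(cm),
    "UQ": lambda cm, design: uq_factors(cm),
    "FullQuantile": lambda cm, design: full_quantile_transform(cm),
    "Median": lambda cm, design: median_factors(cm),
    "PoissonSeq": lambda cm, design: poissonseq_factors(cm, design),
    "RUV": lambda cm, design: ruv_transform(cm, design),
}


def register_normalization(name: str, fn: NormalizationFn, overwrite: bool = False) -> None:
    """Register an additional normalization for the grid.

    The default grid holds eight count-level methods; registering a ninth
    (for example the output of an external read-level normalizer) restores
    a 9 x 5 = 45-cell grid.
    """
    if name in NORMALIZATIONS and not overwrite:
        raise ValueError(f"normalization {name!r} already registered")
    NORMALIZATIONS[name] = fn
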