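"""Per-gene differential expression from case/control replicate matrices.

Three measures are supported, mirroring common microarray practice:

* ``log2_ratio`` — log2 of the ratio of arm means;
* ``t_stat`` — a CyberT-style regularized t statistic whose per-arm variance
  is shrunk toward a background estimated from genes of similar mean
  intensity (a sliding window in intensity-rank order);
* ``sig_log2_ratio`` — the log2 ratio kept only where the regularized-t
  p-value falls below a significance level (default 0.05), else zero.

Matrices are preprocessed linear-scale intensities (genes x replicates);
probe-level preprocessing happens upstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats

log = logging.getLogger(__name__)

__all__ = [
    "ExpressionDataset",
    "DifferentialExpression",
    "log2_ratio",
    "regularized_t",
    "significant_log2_ratio",
    "compute_measure",
    "load_expression",
    "load_measure_table",
]


@dataclass
class ExpressionDataset:
    """Case/control expression intensities for one experiment.

    ``case`` and ``control`` are genes x replicates arrays of positive
    linear-scale intensities with rows aligned to ``genes``.
    """

    genes: tuple[str, ...]
    case: np.ndarray
    control: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        self.case = np.atleast_2d(np.asarray(self.case, dtype=float))
        self.control = np.atleast_2d(np.asarray(self.control, dtype=float))
        n = len(self.genes)
        if self.case.shape[0] != n or self.control.shape[0] != n:
            raise ValueError("expression matrices must have one row per gene")
        if self.case.shape[1] < 1 or self.control.shape[1] < 1:
            raise ValueError("each arm needs at least one replicate")
        if np.any(self.case <= 0) or np.any(self.control <= 0):
            raise ValueError("intensities must be strictly positive (linear scale)")

    @property
    def n_genes(self) -> int:
        return len(self.genes)


@dataclass
class DifferentialExpression:
    """Per-gene differential expression under one measure.

    ``pvalues`` is present for ``t_stat`` and ``sig_log2_ratio``.
    """

    genes: tuple[str, ...]
    values: np.ndarray
    measure: str
    pvalues: np.ndarray | None = None
    _index: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.genes),):
            raise ValueError("values must align with genes")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("differential expression values must be finite")
        if self.pvalues is not None:
            self.pvalues = np.asarray(self.pvalues, dtype=float)
            if self.pvalues.shape != self.values.shape:
                raise ValueError("pvalues must align with genes")
        self._index = {g: i for i, g in enumerate(self.genes)}

    def value(self, gene: str, default: float | None = None) -> float:
        i = self._index.get(gene)
        if i is None:
            if default is None:
                raise KeyError(gene)
            return default
        return float(self.values[i])

    def __contains__(self, gene: str) -> bool:
        return gene in self._index

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.genes, self.values.tolist()))

    def to_table(self, path) -> None:
        df = pd.DataFrame({"gene": self.genes, "value": self.values})
        if self.pvalues is not None:
            df["pvalue"] = self.pvalues
        df.to_csv(path, sep="\t", index=False)


def log2_ratio(ds: ExpressionDataset) -> DifferentialExpression:
    """log2 of mean(case)/mean(control), per gene."""
    mc = ds.case.mean(axis=1)
    mk = ds.control.mean(axis=1)
    bad = (mc <= 0) | (mk <= 0)
    if bad.any():
        names = [g for g, b in zip(ds.genes, bad) if b][:5]
        raise ValueError(f"non-positive mean intensity for gene(s) {names}")
    return DifferentialExpression(ds.genes, np.log2(mc / mk), "log2_ratio")


def _sliding_mean(x: np.ndarray, window: int) -> np.ndarray:
    """Mean of x over a centered window, clipped at the array ends."""
    n = len(x)
    h = window // 2
    cs = np.concatenate(([0.0], np.cumsum(x)))
    lo = np.clip(np.arange(n) - h, 0, n)
    hi = np.clip(np.arange(n) + h + 1, 0, n)
    return (cs[hi] - cs[lo]) / (hi - lo)


def _background_variance(means: np.ndarray, var: np.ndarray, window: int) -> np.ndarray:
    """Per-gene background variance: windowed mean of ``var`` in rank order
    of ``means``.  With single-replicate arms (``var`` all zero from ddof
    starvation) the caller substitutes squared deviations from the local
    window mean, keeping the estimate defined."""
    order = np.argsort(means, kind="stable")
    bg_sorted = _sliding_mean(var[order], window)
    bg = np.empty_like(bg_sorted)
    bg[order] = bg_sorted
    return bg


def regularized_t(
    ds: ExpressionDataset, window: int = 101, prior_df: int = 10
) -> DifferentialExpression:
    """CyberT-style regularized t statistic with Bayesian variance shrinkage.

    Per arm, each gene's sample variance is shrunk toward a background
    variance ``s0^2`` — the mean within-arm variance of the ``window`` genes
    nearest in mean-intensity rank — with ``prior_df`` pseudo-observations:

        s~^2 = (prior_df * s0^2 + (r - 1) * s^2) / (prior_df + r - 1)

    The statistic is a Welch-style t on the shrunken variances, with
    ``(prior_df + r_case - 1) + (prior_df + r_ctrl - 1)`` degrees of freedom
    for the two-sided p-value.  With ``prior_df = 0`` and >= 2 replicates
    per arm this is the ordinary Welch t-test.  Single-replicate arms are
    workable because the background (estimated across genes of similar
    intensity) then supplies the entire variance estimate.
    """
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be odd and >= 3")
    n = ds.n_genes
    if window > n:
        window = max(3, n if n % 2 == 1 else n - 1)
        log.warning("fewer genes than window; shrunk window to %d", window)

    def arm_stats(mat: np.ndarray) -> tuple[np.ndarray, np.ndarray, int]:
        r = mat.shape[1]
        mean = mat.mean(axis=1)
        if r >= 2:
            var = mat.var(axis=1, ddof=1)
        else:
            # background from the spread of single measurements across
            # genes of similar intensity
            order = np.argsort(mean, kind="stable")
            local = _sliding_mean(mean[order], window)
            dev2 = np.empty(n)
            dev2[order] = (mean[order] - local) ** 2
            var = dev2
        s0 = _background_variance(mean, var, window)
        if r >= 2:
            s_reg = (prior_df * s0 + (r - 1) * var) / (prior_df + r - 1)
        else:
            if prior_df <= 0:
                raise ValueError("single-replicate arms require prior_df > 0")
            s_reg = s0
        return mean, s_reg, r

    mc, vc, rc = arm_stats(ds.case)
    mk, vk, rk = arm_stats(ds.control)
    se2 = vc / rc + vk / rk
    num = mc - mk
    t = np.zeros(n)
    nz = se2 > 0
    t[nz] = num[nz] / np.sqrt(se2[nz])
    df = (prior_df + rc - 1) + (prior_df + rk - 1)
    if df <= 0:
        raise ValueError("non-positive degrees of freedom; increase prior_df")
    p = np.ones(n)
    p[nz] = 2.0 * scipy.stats.t.sf(np.abs(t[nz]), df)
    return DifferentialExpression(ds.genes, t, "t_stat", pvalues=p)


def significant_log2_ratio(
    lr: DifferentialExpression,
    t: DifferentialExpression,
    alpha_p: float = 0.05,
) -> DifferentialExpression:
    """Log2 ratio where the regularized-t p-value is below ``alpha_p``, else 0.

    The comparison is strict (a p-value exactly at the threshold is not
    significant); the sign of the ratio is preserved.
    """
    if lr.genes != t.genes:
        raise ValueError("gene sets of the two measures differ")
    if t.pvalues is None:
        raise ValueError("t measure carries no p-values")
    values = np.where(t.pvalues < alpha_p, lr.values, 0.0)
    return DifferentialExpression(lr.genes, values, "sig_log2_ratio", pvalues=t.pvalues)


def compute_measure(
    ds: ExpressionDataset,
    measure: str = "sig_log2_ratio",
    window: int = 101,
    prior_df: int = 10,
    alpha_p: float = 0.05,
) -> DifferentialExpression:
    """Convenience dispatcher for the three measures."""
    if measure == "log2_ratio":
        return log2_ratio(ds)
    if measure == "t_stat":
        return regularized_t(ds, window=window, prior_df=prior_df)
    if measure == "sig_log2_ratio":
        return significant_log2_ratio(
            log2_ratio(ds), regularized_t(ds, window=window, prior_df=prior_df), alpha_p
        )
    raise ValueError(f"unknown measure {measure!r}")


def load_expression(case_path, control_path, name: str = "") -> ExpressionDataset:
    """Load case and control TSVs (first column gene ID, rest replicates)."""
    case = pd.read_csv(case_path, sep="\t", index_col=0)
    ctrl = pd.read_csv(control_path, sep="\t", index_col=0)
    if list(case.index) != list(ctrl.index):
        raise ValueError("case and control files list different genes or orders")
    return ExpressionDataset(
        tuple(str(g) for g in case.index),
        case.to_numpy(float),
        ctrl.to_numpy(float),
        name=name,
    )


def load_measure_table(path, measure: str = "precomputed") -> DifferentialExpression:
    """Load a precomputed ``gene<TAB>value[<TAB>pvalue]`` table."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected at least two columns")
    genes = tuple(str(g) for g in df.iloc[:, 0])
    values = df.iloc[:, 1].to_numpy(float)
    pvals = None
    if "pvalue" in df.columns:
        pvals = df["pvalue"].to_numpy(float)
    return DifferentialExpression(genes, values, measure, pvalues=pvals)
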