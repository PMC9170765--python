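"""Expression pipeline: FPKM, filtering, normalization, covariate removal,
linear-model differential expression, and multi-method DEG intersection.

The differential-expression call mirrors the study's linear-model route:
per-gene ordinary least squares of log2 normalized FPKM on a case/control
indicator plus development-day, breed and sequencing-lane covariates, a
two-sided t-test on the group coefficient, and Benjamini–Hochberg FDR at
q < 0.05.  External caller results (e.g. Cuffdiff, DESeq2 gene lists) are
consumed as id lists and intersected with the linear-model calls.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("piaoscan")

__all__ = [
    "ExpressionSet",
    "NormalizedMatrix",
    "compute_fpkm",
    "filter_expressed",
    "normalize_log2",
    "encode_covariates",
    "adjust_covariates",
    "lm_deg",
    "bh_fdr",
    "fold_change",
    "welch_degs",
    "intersect_degs",
]


@dataclass
class ExpressionSet:
    """Counts from the two counting models plus FPKM, annotations, metadata.

    All matrices are gene × sample DataFrames sharing indices.  ``gene_meta``
    carries length (bp) and gc (fraction); ``sample_meta`` carries group
    ∈ {case, control}, day, breed, lane; ``lib_size`` the per-sample mapped
    fragment totals.
    """

    counts_union: pd.DataFrame
    counts_whole: pd.DataFrame
    fpkm: pd.DataFrame
    gene_meta: pd.DataFrame
    sample_meta: pd.DataFrame
    lib_size: pd.Series

    def __post_init__(self) -> None:
        for name, m in (("counts_whole", self.counts_whole), ("fpkm", self.fpkm)):
            if not m.index.equals(self.counts_union.index) or not m.columns.equals(
                self.counts_union.columns
            ):
                raise ValueError(f"{name} does not share counts_union indices")
        if (self.gene_meta["length"] <= 0).any():
            raise ValueError("gene lengths must be > 0")
        if ((self.gene_meta["gc"] < 0) | (self.gene_meta["gc"] > 1)).any():
            raise ValueError("GC fractions must lie in [0, 1]")


@dataclass
class NormalizedMatrix:
    """log2-scale gene × sample values with provenance flags."""

    values: pd.DataFrame
    gc_corrected: bool = False
    covariates_removed: list = field(default_factory=list)


def compute_fpkm(counts_union, gene_length, lib_size=None) -> pd.DataFrame:
    """FPKM = counts · 10⁹ / (length · lib_size).

    ``lib_size`` defaults to the per-sample column sums of ``counts_union``.
    """
    counts = pd.DataFrame(counts_union)
    length = pd.Series(gene_length).reindex(counts.index)
    if (length <= 0).any():
        raise ValueError("gene lengths must be > 0")
    if lib_size is None:
        lib_size = counts.sum(axis=0)
    lib_size = pd.Series(lib_size).reindex(counts.columns)
    zero = lib_size[lib_size <= 0]
    if len(zero):
        raise ValueError(f"zero library size for samples: {list(zero.index)}")
    return counts * 1e9 / np.outer(length.to_numpy(), lib_size.to_numpy())


def filter_expressed(eset: ExpressionSet, frac: float = 0.8, min_count: int = 10) -> list:
    """Genes expressed in ≥ ``frac`` of the case or of the control samples.

    A sample supports a gene iff counts_union ≥ min_count AND counts_whole ≥
    min_count AND fpkm > 0; the gene is retained iff its supporting samples
    cover at least ``frac`` of the case samples or of the control samples
    (fractional comparison, no rounding).
    """
    support = (
        (eset.counts_union >= min_count)
        & (eset.counts_whole >= min_count)
        & (eset.fpkm > 0)
    )
    keep = pd.Series(False, index=eset.counts_union.index)
    for grp in ("case", "control"):
        cols = eset.sample_meta.index[eset.sample_meta["group"] == grp]
        if len(cols):
            keep |= support[cols].sum(axis=1) / len(cols) >= frac
    return list(keep.index[keep])


def normalize_log2(
    fpkm: pd.DataFrame,
    gene_meta: pd.DataFrame | None = None,
    gc_correct: bool = False,
    offset: float = 1.0,
) -> NormalizedMatrix:
    """log2(FPKM + offset), optionally detrended for GC content and length.

    The correction fits, per sample, a robust (Huber) regression of the
    log2 value on GC fraction and log10 length and subtracts the centred fit,
    removing systematic GC/length trends while preserving each sample's mean.
    This is a transparent surrogate for spline-based conditional-quantile
    normalization; it targets linear trends only.
    """
    if offset <= 0 and (fpkm.to_numpy() <= 0).any():
        raise ValueError("offset must be > 0 when fpkm contains zeros")
    values = np.log2(fpkm + offset)
    if not gc_correct:
        return NormalizedMatrix(values, gc_corrected=False)
    if gene_meta is None:
        raise ValueError("gc_correct requires gene_meta with length and gc")
    import statsmodels.api as sm

    meta = gene_meta.reindex(values.index)
    X = sm.add_constant(
        np.column_stack([meta["gc"].to_numpy(), np.log10(meta["length"].to_numpy())])
    )
    corrected = values.copy()
    for col in values.columns:
        y = values[col].to_numpy()
        fit = sm.RLM(y, X, M=sm.robust.norms.HuberT()).fit()
        trend = fit.fittedvalues
        corrected[col] = y - (trend - trend.mean())
    return NormalizedMatrix(corrected, gc_corrected=True)


def encode_covariates(
    sample_meta: pd.DataFrame,
    day: bool = True,
    breed: bool = True,
    lane: bool = True,
) -> pd.DataFrame:
    """Numeric covariate encodings for adjustment and the DEG linear model.

    Days D7/D8/D9 are coded 1/2/3.  Breed is encoded as a contrast among
    control subtypes only (first control breed as reference, case samples at
    the reference level): in this design breed would otherwise be perfectly
    confounded with case/control.  Lanes are one-hot with the first level as
    reference.  The group label itself is never included.
    """
    out = {}
    if day:
        codes = sorted(sample_meta["day"].unique())
        out["day"] = sample_meta["day"].map({d: i + 1 for i, d in enumerate(codes)})
    if breed:
        case_breeds = set(sample_meta.loc[sample_meta["group"] == "case", "breed"])
        ctrl_levels = sorted(
            b for b in sample_meta["breed"].unique() if b not in case_breeds
        )
        for level in ctrl_levels[1:]:
            out[f"breed_{level}"] = (sample_meta["breed"] == level).astype(float)
    if lane:
        levels = sorted(sample_meta["lane"].unique())
        for level in levels[1:]:
            out[f"lane_{level}"] = (sample_meta["lane"] == level).astype(float)
    return pd.DataFrame(out, index=sample_meta.index, dtype=float)


def _check_design(X: np.ndarray, names: list) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # pivoted QR localizes the dependent columns
        from scipy.linalg import qr

        _, _, piv = qr(X, pivoting=True)
        collinear = [names[j] for j in sorted(piv[rank:])]
        raise ValueError(f"collinear design columns: {collinear}")


def adjust_covariates(matrix, covariates: pd.DataFrame):
    """Remove per-gene covariate contributions by ordinary least squares.

    For each gene, fit value ~ intercept + covariates and subtract
    Σ_c β̂_c·x_c; the intercept and the residual are retained.  Adjusting a
    second time with the same covariates is a no-op (residuals are orthogonal
    to the design).  Collinear covariates (including any constant column,
    which duplicates the intercept) raise an error naming the offending set.
    """
    values = matrix.values if isinstance(matrix, NormalizedMatrix) else matrix
    cov = covariates.reindex(values.columns)
    if cov.isna().any().any():
        raise ValueError("covariates must cover every sample")
    Xc = cov.to_numpy(dtype=float)
    X = np.column_stack([np.ones(len(cov)), Xc])
    _check_design(X, ["intercept"] + list(cov.columns))
    Y = values.to_numpy(dtype=float)  # genes × samples
    beta = np.linalg.lstsq(X, Y.T, rcond=None)[0]  # p × genes
    adjusted = Y - (Xc @ beta[1:]).T
    out = pd.DataFrame(adjusted, index=values.index, columns=values.columns)
    removed = list(cov.columns)
    if isinstance(matrix, NormalizedMatrix):
        return NormalizedMatrix(out, matrix.gc_corrected,
                                matrix.covariates_removed + removed)
    return NormalizedMatrix(out, covariates_removed=removed)


def lm_deg(matrix, group: pd.Series, covariates: pd.DataFrame | None = None,
           alpha: float = 0.05) -> pd.DataFrame:
    """Per-gene linear-model differential expression test.

    Fits value ~ intercept + group + covariates by OLS for every gene
    (vectorized across genes, shared design), tests the group coefficient
    with a two-sided t-test on n − p residual degrees of freedom, and
    converts p values to Benjamini–Hochberg q values.  Returns a DataFrame
    with coef (log2 scale, case minus control), fold_change = 2^coef,
    p, q and the deg flag (q < alpha).
    """
    values = matrix.values if isinstance(matrix, NormalizedMatrix) else matrix
    group = pd.Series(group).reindex(values.columns)
    g = (group == "case").astype(float).to_numpy() if group.dtype == object \
        else group.to_numpy(dtype=float)
    for label in ("case", "control"):
        if group.dtype == object and (group == label).sum() < 2:
            raise ValueError(f"need ≥ 2 samples in group {label!r}")
    cols = [np.ones(len(g)), g]
    names = ["intercept", "group"]
    if covariates is not None and covariates.shape[1]:
        cov = covariates.reindex(values.columns)
        cols.append(cov.to_numpy(dtype=float))
        names += list(cov.columns)
        X = np.column_stack(cols)
    else:
        X = np.column_stack(cols)
    _check_design(X, names)
    n, p = X.shape
    df = n - p
    if df < 1:
        raise ValueError("residual degrees of freedom < 1")

    Y = values.to_numpy(dtype=float)
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ X.T @ Y.T  # p × genes
    resid = Y.T - X @ beta
    sigma2 = (resid**2).sum(axis=0) / df
    se = np.sqrt(np.maximum(sigma2 * xtx_inv[1, 1], 0.0))
    coef = beta[1]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, coef / np.where(se > 0, se, 1.0), 0.0)
    pvals = 2.0 * stats.t.sf(np.abs(t), df)
    qvals = bh_fdr(pvals)
    return pd.DataFrame(
        {
            "coef": coef,
            "fold_change": np.exp2(coef),
            "t": t,
            "p": pvals,
            "q": qvals,
            "deg": qvals < alpha,
        },
        index=values.index,
    )


def bh_fdr(p) -> np.ndarray:
    """Benjamini–Hochberg step-up q values."""
    p = np.asarray(p, dtype=float)
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p values must lie in [0, 1]")
    from statsmodels.stats.multitest import multipletests

    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def fold_change(fpkm: pd.DataFrame, group: pd.Series, pseudo: float = 0.01) -> pd.DataFrame:
    """Group-mean FPKM fold change, reported with the higher group's label.

    FC = (mean of the higher group + pseudo) / (mean of the lower group +
    pseudo); the pseudo-count keeps ratios finite for genes that are almost
    undetectable in one group.
    """
    group = pd.Series(group).reindex(fpkm.columns)
    case_cols = fpkm.columns[group == "case"]
    ctrl_cols = fpkm.columns[group == "control"]
    if not len(case_cols) or not len(ctrl_cols):
        raise ValueError("both groups must be non-empty")
    m_case = fpkm[case_cols].mean(axis=1)
    m_ctrl = fpkm[ctrl_cols].mean(axis=1)
    hi = np.maximum(m_case, m_ctrl)
    lo = np.minimum(m_case, m_ctrl)
    fc = (hi + pseudo) / (lo + pseudo)
    direction = np.where(m_case >= m_ctrl, "case", "control")
    return pd.DataFrame(
        {"mean_case": m_case, "mean_control": m_ctrl, "fc": fc,
         "higher": direction},
        index=fpkm.index,
    )


def welch_degs(matrix, group: pd.Series, alpha: float = 0.05) -> pd.DataFrame:
    """Welch t-test DEG caller on normalized values with BH FDR.

    A deliberately simple second caller used to exercise multi-method
    intersection; it is not a reimplementation of any count-based method.
    """
    values = matrix.values if isinstance(matrix, NormalizedMatrix) else matrix
    group = pd.Series(group).reindex(values.columns)
    a = values.loc[:, (group == "case").to_numpy()].to_numpy()
    b = values.loc[:, (group == "control").to_numpy()].to_numpy()
    t, p = stats.ttest_ind(a, b, axis=1, equal_var=False)
    p = np.nan_to_num(p, nan=1.0)
    q = bh_fdr(p)
    return pd.DataFrame({"t": t, "p": p, "q": q, "deg": q < alpha},
                        index=values.index)


@dataclass
class IntersectionReport:
    final: set
    set_sizes: dict
    overlaps: dict  # frozenset of names → overlap count


def intersect_degs(sets: dict, universe=None) -> IntersectionReport:
    """Intersect ≥ 2 named DEG id sets; report the Venn counts.

    ``universe``, if given, is the set of known gene ids; members of an
    external list outside it are excluded with a logged count.
    """
    if len(sets) < 2:
        raise ValueError("need at least two named DEG sets")
    clean = {}
    for name, ids in sets.items():
        s = set(ids)
        if universe is not None:
            unknown = s - set(universe)
            if unknown:
                logger.warning(
                    "%s: %d unknown gene ids excluded", name, len(unknown)
                )
                s -= unknown
        clean[name] = s
    names = list(clean)
    final = set.intersection(*clean.values())
    overlaps = {}
    from itertools import combinations

    for k in range(2, len(names) + 1):
        for combo in combinations(names, k):
            overlaps[frozenset(combo)] = len(set.intersection(*(clean[c] for c in combo)))
    return IntersectionReport(
        final=final,
        set_sizes={n: len(s) for n, s in clean.items()},
        overlaps=overlaps,
    )
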