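"""Signed weighted co-expression network with topological overlap.

Builds the network arm of the analysis: signed adjacency
a_ij = ((1 + cor_ij)/2)^β with soft power chosen by the scale-free topology
fit, the topological overlap matrix (TOM), average-linkage module detection
on 1 − TOM, eigengene-based module merging at a height cut of 0.25,
module–trait Pearson correlation, and hub-gene calling by gene significance
(GS), module membership (kME) and intramodular connectivity (kIM), with a
thresholded edge export for the top hubs.

Module detection replaces the dynamic tree cut of the reference WGCNA
workflow with a deterministic static cut at an absolute dissimilarity
height; modules are validated by planted-structure recovery rather than by
gene-for-gene agreement with any particular tree-cut heuristic.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

logger = logging.getLogger("piaoscan")

__all__ = [
    "ModuleSet",
    "correlation_matrix",
    "signed_adjacency",
    "connectivity",
    "soft_power_fit",
    "topological_overlap",
    "detect_modules",
    "module_eigengene",
    "module_eigengenes",
    "merge_modules",
    "module_trait",
    "hub_selection",
]

UNASSIGNED = "M0"


@dataclass
class ModuleSet:
    """Gene → module assignment; ``M0`` collects unassigned genes."""

    assignment: pd.Series
    merge_history: list = field(default_factory=list)

    def modules(self) -> list:
        labels = [m for m in self.assignment.unique() if m != UNASSIGNED]
        return sorted(labels, key=lambda m: int(m[1:]))

    def members(self, label: str) -> pd.Index:
        return self.assignment.index[self.assignment == label]


def correlation_matrix(expr: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation between gene expression profiles (gene × sample in)."""
    with np.errstate(invalid="ignore"):
        cor = np.corrcoef(expr.to_numpy(dtype=float))
    cor = np.nan_to_num(cor, nan=0.0)
    np.fill_diagonal(cor, 1.0)
    return pd.DataFrame(cor, index=expr.index, columns=expr.index)


def signed_adjacency(cor_matrix, beta: int = 12) -> pd.DataFrame:
    """Signed adjacency a_ij = ((1 + cor_ij)/2)^β, diagonal fixed at 1."""
    cor = pd.DataFrame(cor_matrix)
    c = cor.to_numpy(dtype=float)
    if np.abs(c).max() > 1 + 1e-8:
        raise ValueError("correlations must lie in [-1, 1]")
    c = np.clip(c, -1.0, 1.0)
    a = ((1.0 + c) / 2.0) ** beta
    np.fill_diagonal(a, 1.0)
    return pd.DataFrame(a, index=cor.index, columns=cor.columns)


def connectivity(adjacency: pd.DataFrame) -> pd.Series:
    """Whole-network connectivity k_i = Σ_{j≠i} a_ij."""
    a = adjacency.to_numpy(dtype=float)
    return pd.Series(a.sum(axis=1) - np.diag(a), index=adjacency.index)


def _scale_free_rsq(k: np.ndarray, n_bins: int = 10):
    """R² of log10(frequency) on log10(mean k) over equal-width bins of k."""
    k = np.asarray(k, dtype=float)
    k = k[k > 0]
    if len(k) < n_bins or np.ptp(k) < 1e-12:
        return 0.0, 0.0
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    idx = np.clip(np.searchsorted(edges, k, side="right") - 1, 0, len(edges) - 2)
    log_freq, log_k = [], []
    for b in range(len(edges) - 1):
        members = k[idx == b]
        if len(members):
            log_freq.append(np.log10(len(members) / len(k)))
            log_k.append(np.log10(members.mean()))
    if len(log_k) < 3:
        return 0.0, 0.0
    res = stats.linregress(log_k, log_freq)
    if not np.isfinite(res.rvalue):
        return 0.0, 0.0
    return float(res.rvalue**2), float(res.slope)


def soft_power_fit(expr: pd.DataFrame, powers=range(1, 21), rsq_target: float = 0.8,
                   n_bins: int = 10):
    """Scale-free topology fit per candidate soft power.

    For each power, builds the signed adjacency, bins connectivity into
    ``n_bins`` equal-width bins and regresses log10(frequency) on
    log10(mean k); the chosen power is the first whose R² exceeds
    ``rsq_target``, else the argmax (with a warning).  Degenerate
    connectivity (all equal) reports R² = 0 with a warning.
    """
    if len(expr) < 10:
        raise ValueError("need at least 10 genes for the scale-free fit")
    cor = correlation_matrix(expr)
    rows = []
    for beta in powers:
        a = signed_adjacency(cor, beta=beta)
        k = connectivity(a).to_numpy()
        if np.ptp(k) < 1e-12:
            warnings.warn(f"degenerate connectivity at power {beta}; R² set to 0")
            rows.append((beta, 0.0, 0.0, float(k.mean())))
            continue
        rsq, slope = _scale_free_rsq(k, n_bins=n_bins)
        rows.append((beta, rsq, slope, float(k.mean())))
    table = pd.DataFrame(rows, columns=["power", "rsq", "slope", "mean_k"])
    hit = table.index[table["rsq"] > rsq_target]
    if len(hit):
        chosen = int(table.loc[hit[0], "power"])
    else:
        chosen = int(table.loc[table["rsq"].idxmax(), "power"])
        warnings.warn(
            f"no power reached R² > {rsq_target}; falling back to {chosen}"
        )
    return table, chosen


def topological_overlap(adjacency) -> pd.DataFrame:
    """Topological overlap matrix for a signed adjacency with unit diagonal.

        TOM_ij = (Σ_{u≠i,j} a_iu·a_uj + a_ij) / (min(k_i, k_j) + 1 − a_ij)

    with TOM_ii = 1 and k the connectivity excluding the diagonal.
    """
    A = pd.DataFrame(adjacency)
    a = A.to_numpy(dtype=float)
    if np.abs(np.diag(a) - 1.0).max() > 1e-8:
        raise ValueError("adjacency diagonal must be 1")
    k = a.sum(axis=1) - 1.0
    shared = a @ a - 2.0 * a  # Σ_{u≠i,j} a_iu a_uj  (diagonal terms removed)
    num = shared + a
    den = np.minimum.outer(k, k) + 1.0 - a
    with np.errstate(divide="ignore", invalid="ignore"):
        tom = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    np.fill_diagonal(tom, 1.0)
    tom = np.clip((tom + tom.T) / 2.0, 0.0, 1.0)
    return pd.DataFrame(tom, index=A.index, columns=A.columns)


def detect_modules(tom: pd.DataFrame, min_size: int = 30,
                   cut_height: float = 0.85) -> ModuleSet:
    """Average-linkage clustering on 1 − TOM with a static height cut.

    Clusters with ≥ ``min_size`` genes become modules M1, M2, … ordered by
    decreasing size (ties by first gene index); all remaining genes fall in
    M0.  ``cut_height`` is an absolute dissimilarity threshold: tightly
    co-expressed blocks join well below it while merges among unrelated
    genes concentrate near 1 − TOM ≈ 1 and are never cut into modules.
    """
    genes = tom.index
    if len(genes) < min_size:
        return ModuleSet(pd.Series(UNASSIGNED, index=genes, name="module"))
    dissim = 1.0 - tom.to_numpy(dtype=float)
    np.fill_diagonal(dissim, 0.0)
    Z = linkage(squareform(dissim, checks=False), method="average")
    flat = fcluster(Z, t=cut_height, criterion="distance")
    assignment = pd.Series(UNASSIGNED, index=genes, name="module")
    clusters = []
    for label in np.unique(flat):
        rows = np.flatnonzero(flat == label)
        if len(rows) >= min_size:
            clusters.append((len(rows), rows[0], rows))
    clusters.sort(key=lambda c: (-c[0], c[1]))
    for rank, (_, _, rows) in enumerate(clusters, start=1):
        assignment.iloc[rows] = f"M{rank}"
    return ModuleSet(assignment)


def _standardize(expr: pd.DataFrame) -> np.ndarray:
    x = expr.to_numpy(dtype=float)
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    sd = np.where(sd > 0, sd, 1.0)
    return (x - mu) / sd


def module_eigengene(expr: pd.DataFrame, genes) -> pd.Series:
    """First principal component of a module's standardized submatrix.

    Returned per sample with unit norm, sign-oriented so that it correlates
    non-negatively with the module's mean standardized expression.  A
    single-gene module yields that gene's standardized profile (unit norm).
    """
    sub = expr.loc[list(genes)]
    if len(sub) == 0:
        raise ValueError("module is empty")
    xs = _standardize(sub)
    _, _, vt = np.linalg.svd(xs, full_matrices=False)
    me = vt[0]
    mean_profile = xs.mean(axis=0)
    if np.dot(me, mean_profile) < 0:
        me = -me
    norm = np.linalg.norm(me)
    return pd.Series(me / (norm if norm > 0 else 1.0), index=expr.columns)


def module_eigengenes(expr: pd.DataFrame, modules: ModuleSet) -> pd.DataFrame:
    """Sample × module eigengene matrix (M0 excluded)."""
    mes = {
        label: module_eigengene(expr, modules.members(label))
        for label in modules.modules()
    }
    return pd.DataFrame(mes, index=expr.columns)


def merge_modules(expr: pd.DataFrame, modules: ModuleSet,
                  merge_height: float = 0.25) -> ModuleSet:
    """Iteratively merge modules whose eigengenes correlate above 1 − height.

    At each step the pair with the highest eigengene correlation is merged
    (ties broken toward smaller module indices), eigengenes are recomputed,
    and the process repeats while the best correlation exceeds
    1 − ``merge_height`` (0.75 at the default height cut of 0.25).  Final
    labels are reassigned by decreasing module size.  Running a second pass
    with the same height merges nothing.
    """
    assignment = modules.assignment.copy()
    history = list(modules.merge_history)
    threshold = 1.0 - merge_height

    def current_labels():
        return sorted(
            (m for m in assignment.unique() if m != UNASSIGNED),
            key=lambda m: int(m[1:]),
        )

    while True:
        labels = current_labels()
        if len(labels) < 2:
            break
        mes = pd.DataFrame(
            {
                m: module_eigengene(expr, assignment.index[assignment == m])
                for m in labels
            }
        )
        cor = mes.corr()
        best, best_pair = -np.inf, None
        for i, mi in enumerate(labels):
            for mj in labels[i + 1:]:
                c = cor.loc[mi, mj]
                if c > best + 1e-12:
                    best, best_pair = c, (mi, mj)
        if best_pair is None or best <= threshold:
            break
        mi, mj = best_pair
        assignment[assignment == mj] = mi
        history.append((mi, mj, float(best)))

    labels = current_labels()
    sizes = [((assignment == m).sum(), m) for m in labels]
    sizes.sort(key=lambda t: (-t[0], int(t[1][1:])))
    relabel = {old: f"M{rank}" for rank, (_, old) in enumerate(sizes, start=1)}
    final = assignment.map(lambda m: relabel.get(m, UNASSIGNED))
    final.name = "module"
    return ModuleSet(final, merge_history=history)


def module_trait(mes: pd.DataFrame, trait: pd.Series,
                 alpha: float = 0.05) -> pd.DataFrame:
    """Pearson correlation of each module eigengene with a binary trait.

    The trait is coded case = 1, control = 0.  p values come from
    t = r·√((n−2)/(1−r²)) on n − 2 degrees of freedom, two-sided;
    ``significant`` flags p < alpha.
    """
    trait = pd.Series(trait).reindex(mes.index).astype(float)
    if trait.nunique() < 2:
        raise ValueError("trait is constant across samples")
    if len(trait) < 3:
        raise ValueError("need at least 3 samples")
    rows = []
    for m in mes.columns:
        r, p = stats.pearsonr(mes[m], trait)
        rows.append((m, r, p, p < alpha))
    return pd.DataFrame(rows, columns=["module", "r", "p", "significant"]) \
        .set_index("module")


def _cor_with_vector(expr: pd.DataFrame, v: np.ndarray) -> np.ndarray:
    x = _standardize(expr)
    vs = (v - v.mean()) / (v.std() if v.std() > 0 else 1.0)
    return x @ vs / len(vs)


def hub_selection(
    expr: pd.DataFrame,
    trait: pd.Series,
    modules: ModuleSet,
    adjacency: pd.DataFrame,
    tom: pd.DataFrame,
    gs_min: float = 0.2,
    kme_min: float = 0.8,
    top_n: int = 50,
    tom_edge: float = 0.1,
):
    """Hub genes per module and thresholded edge lists among the top hubs.

    GS is the correlation of each gene with the trait, kME the correlation
    with its module's eigengene, kIM the summed adjacency to same-module
    members.  Hubs satisfy |GS| > gs_min AND |kME| > kme_min (strict), are
    ranked by kIM descending (ties by gene id), and the unordered pairs
    among each module's top ``top_n`` hubs with TOM > ``tom_edge`` are
    exported as (source, target, weight) rows.
    """
    trait = pd.Series(trait).reindex(expr.columns).astype(float)
    gs = pd.Series(_cor_with_vector(expr, trait.to_numpy()), index=expr.index)
    mes = module_eigengenes(expr, modules)
    a = adjacency.to_numpy(dtype=float)

    records = []
    edges: dict[str, pd.DataFrame] = {}
    gene_pos = {g: i for i, g in enumerate(expr.index)}
    for label in modules.modules():
        members = list(modules.members(label))
        rows = np.array([gene_pos[g] for g in members])
        kme = pd.Series(
            _cor_with_vector(expr.loc[members], mes[label].to_numpy()),
            index=members,
        )
        sub = a[np.ix_(rows, rows)]
        kim = pd.Series(sub.sum(axis=1) - np.diag(sub), index=members)
        for g in members:
            records.append((g, label, gs[g], kme[g], kim[g],
                            abs(gs[g]) > gs_min and abs(kme[g]) > kme_min))
        hub_genes = [g for g in members
                     if abs(gs[g]) > gs_min and abs(kme[g]) > kme_min]
        hub_genes.sort(key=lambda g: (-kim[g], g))
        top = hub_genes[:top_n]
        pairs = []
        for i, gi in enumerate(top):
            for gj in top[i + 1:]:
                w = float(tom.loc[gi, gj])
                if w > tom_edge:
                    pairs.append((gi, gj, w))
        edges[label] = pd.DataFrame(pairs, columns=["source", "target", "weight"])

    hub_table = pd.DataFrame(
        records, columns=["gene", "module", "gs", "kme", "kim", "hub"]
    ).set_index("gene")
    hub_table = hub_table.sort_values(["module", "kim"], ascending=[True, False])
    return hub_table, edges
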