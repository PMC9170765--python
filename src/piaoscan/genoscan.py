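"""Case/control selection scan on biallelic genotype matrices.

Implements the genomic arm of the rumpless-chicken analysis design: per-site
nucleotide diversity (Pi) and fixation index (FST), 40-kb sliding windows
stepped every 20 kb, ΔPi = Pi(control) − Pi(case), top-1% candidate
intersection, a control-subsampling recovery-ratio (RR) validation, and the
genotype-frequency (GF) filter for highly differentiated SNPs/indels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("piaoscan")

MISSING = -1  # genotype code for a missing call

__all__ = [
    "GenotypeMatrix",
    "CandidateSet",
    "read_vcf",
    "read_panel",
    "site_pi",
    "site_fst",
    "window_scan",
    "select_candidates",
    "recovery_ratio",
    "differentiated_sites",
]


# ---------------------------------------------------------------------------
# containers

@dataclass
class GenotypeMatrix:
    """Biallelic site × individual genotype codes with a population panel.

    ``sites`` has columns (chrom, pos, ref, alt, site_type) with 1-based
    positions strictly increasing within each chromosome; ``site_type`` is
    "SNP" or "indel".  ``genotypes`` holds copy-number-of-alt codes
    0 (hom-ref), 1 (het), 2 (hom-alt) and −1 for missing.  ``panel`` is
    indexed by sample id with a ``population`` column in {case, control}
    (optional ``subgroup``); its order matches the genotype columns.
    """

    sites: pd.DataFrame
    genotypes: np.ndarray
    panel: pd.DataFrame

    def __post_init__(self) -> None:
        if self.genotypes.ndim != 2:
            raise ValueError("genotypes must be 2-D (sites × individuals)")
        if len(self.sites) != self.genotypes.shape[0]:
            raise ValueError("sites/genotypes row mismatch")
        if len(self.panel) != self.genotypes.shape[1]:
            raise ValueError("panel/genotypes column mismatch")
        bad = set(self.panel["population"]) - {"case", "control"}
        if bad:
            raise ValueError(f"unknown population labels: {sorted(bad)}")
        for chrom, grp in self.sites.groupby("chrom", sort=False):
            if not np.all(np.diff(grp["pos"].to_numpy()) > 0):
                raise ValueError(f"positions not strictly increasing on {chrom}")

    @property
    def n_sites(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[1]

    def population_columns(self, population: str) -> np.ndarray:
        """Column indices of the individuals in ``population``."""
        return np.flatnonzero((self.panel["population"] == population).to_numpy())

    def site_ids(self) -> pd.Series:
        return self.sites["chrom"].astype(str) + ":" + self.sites["pos"].astype(str)


@dataclass
class CandidateSet:
    """Top-1% intersection candidates with optional RR validation fields.

    ``table`` is indexed by window id ("chrom:start") and carries fst,
    delta_pi and, after :func:`recovery_ratio`, rr_fst / rr_dpi / rr_joint
    and the final ``selected`` flag.
    """

    fst_threshold: float
    dpi_threshold: float
    top_fst: frozenset
    top_dpi: frozenset
    table: pd.DataFrame
    n_replicates: int = 0
    rr_min: float = field(default=0.95)

    @property
    def candidate_ids(self) -> list:
        return list(self.table.index)


# ---------------------------------------------------------------------------
# input

def read_panel(path) -> pd.DataFrame:
    """Read a sample-panel TSV with columns sample_id, population[, subgroup]."""
    panel = pd.read_csv(path, sep="\t", dtype=str)
    if "sample_id" not in panel.columns or "population" not in panel.columns:
        raise ValueError("panel must have columns sample_id and population")
    return panel.set_index("sample_id")


def read_vcf(path, panel) -> GenotypeMatrix:
    """Load a VCF with GT fields into a :class:`GenotypeMatrix`.

    ``panel`` is a path to a panel TSV or a DataFrame indexed by sample id.
    Genotypes map 0/0→0, 0/1 or 1/0→1, 1/1→2; phase separators are ignored
    and any missing allele yields the missing code.  Records with more than
    one ALT allele are dropped (counted in the log).  A site is typed SNP
    iff both REF and ALT are single bases.
    """
    from cyvcf2 import VCF

    if not isinstance(panel, pd.DataFrame):
        panel = read_panel(panel)

    vcf = VCF(str(path), gts012=False)
    samples = list(vcf.samples)
    unknown = [s for s in samples if s not in panel.index]
    if unknown:
        raise ValueError(f"samples in VCF absent from panel: {unknown}")

    rows, codes = [], []
    n_multi = 0
    for variant in vcf:
        if len(variant.ALT) != 1:
            n_multi += 1
            continue
        ref, alt = variant.REF, variant.ALT[0]
        site_type = "SNP" if len(ref) == 1 and len(alt) == 1 else "indel"
        gt = np.full(len(samples), MISSING, dtype=np.int8)
        for i, g in enumerate(variant.genotypes):
            a, b = g[0], g[1]
            if a >= 0 and b >= 0:
                gt[i] = a + b
        rows.append((variant.CHROM, variant.POS, ref, alt, site_type))
        codes.append(gt)
    vcf.close()
    if n_multi:
        logger.warning("dropped %d multiallelic records", n_multi)

    sites = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "site_type"])
    genotypes = (
        np.vstack(codes) if codes else np.empty((0, len(samples)), dtype=np.int8)
    )
    return GenotypeMatrix(sites, genotypes, panel.loc[samples])


# ---------------------------------------------------------------------------
# per-site statistics

def _allele_stats(genotypes: np.ndarray, cols: np.ndarray):
    """Per-site (called allele count m, alt allele count) for a column subset."""
    sub = genotypes[:, cols]
    called = (sub != MISSING).sum(axis=1)
    alt = np.where(sub != MISSING, sub, 0).sum(axis=1)
    return 2 * called, alt


def site_pi(alt_count, n_alleles):
    """Unbiased per-site nucleotide diversity (m/(m−1))·2p̂(1−p̂).

    Equals the mean number of differences over all C(m,2) pairs of sampled
    alleles at the site.  Entries with fewer than two called alleles return
    0.0 and are meant to be excluded from window sums by the caller.
    """
    m = np.asarray(n_alleles, dtype=float)
    alt = np.asarray(alt_count, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(m > 0, alt / m, 0.0)
        pi = np.where(m >= 2, m / np.maximum(m - 1, 1) * 2.0 * p * (1.0 - p), 0.0)
    return pi


def site_fst(p1, m1, p2, m2, estimator: str = "hudson", het1=None, het2=None):
    """Per-site FST components (numerator, denominator) for two populations.

    ``p`` are alt-allele frequencies, ``m`` called allele counts.  The Hudson
    two-population estimator is the default:

        N = (p1 − p2)² − p1(1 − p1)/(m1 − 1) − p2(1 − p2)/(m2 − 1)
        D = p1(1 − p2) + p2(1 − p1)

    ``wc84`` computes the Weir–Cockerham (1984) variance components for two
    populations, returning (a, a + b + c); it needs the observed heterozygote
    frequency of each population (``het1``/``het2``).  Window-level FST should
    be formed as ratio of sums over sites; per-site ratios may be negative.
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    m1 = np.asarray(m1, dtype=float)
    m2 = np.asarray(m2, dtype=float)
    if estimator == "hudson":
        with np.errstate(divide="ignore", invalid="ignore"):
            num = (
                (p1 - p2) ** 2
                - p1 * (1 - p1) / np.maximum(m1 - 1, 1e-300)
                - p2 * (1 - p2) / np.maximum(m2 - 1, 1e-300)
            )
        den = p1 * (1 - p2) + p2 * (1 - p1)
        return num, den
    if estimator == "wc84":
        if het1 is None or het2 is None:
            raise ValueError("wc84 requires observed heterozygosities het1, het2")
        h1 = np.asarray(het1, dtype=float)
        h2 = np.asarray(het2, dtype=float)
        n1, n2 = m1 / 2.0, m2 / 2.0  # individuals
        r = 2.0
        nbar = (n1 + n2) / r
        with np.errstate(divide="ignore", invalid="ignore"):
            nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
            pbar = (n1 * p1 + n2 * p2) / (r * nbar)
            s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
            hbar = (n1 * h1 + n2 * h2) / (r * nbar)
            a = (nbar / nc) * (
                s2
                - (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4.0)
                / np.maximum(nbar - 1, 1e-300)
            )
            b = (nbar / np.maximum(nbar - 1, 1e-300)) * (
                pbar * (1 - pbar)
                - s2 * (r - 1) / r
                - hbar * (2 * nbar - 1) / (4 * nbar)
            )
            c = hbar / 2.0
        return a, a + b + c
    raise ValueError(f"unknown estimator: {estimator!r}")


def _site_arrays(matrix: GenotypeMatrix, case_cols, control_cols, estimator):
    """Per-site pi (both populations) and FST components, with validity masks."""
    m1, a1 = _allele_stats(matrix.genotypes, case_cols)
    m2, a2 = _allele_stats(matrix.genotypes, control_cols)
    return _site_arrays_from_counts(matrix.genotypes, case_cols, control_cols,
                                    m1, a1, m2, a2, estimator)


def _site_arrays_from_counts(genotypes, case_cols, control_cols,
                             m1, a1, m2, a2, estimator):
    valid1 = m1 >= 2
    valid2 = m2 >= 2
    pi_case = np.where(valid1, site_pi(a1, m1), 0.0)
    pi_control = np.where(valid2, site_pi(a2, m2), 0.0)

    with np.errstate(divide="ignore", invalid="ignore"):
        p1 = np.where(m1 > 0, a1 / m1, 0.0)
        p2 = np.where(m2 > 0, a2 / m2, 0.0)
    kwargs = {}
    if estimator == "wc84":
        het = lambda cols, m: np.where(  # noqa: E731
            m > 0, (genotypes[:, cols] == 1).sum(axis=1) / np.maximum(m / 2, 1), 0.0
        )
        kwargs = {"het1": het(case_cols, m1), "het2": het(control_cols, m2)}
    num, den = site_fst(p1, np.maximum(m1, 2), p2, np.maximum(m2, 2),
                        estimator=estimator, **kwargs)
    both = valid1 & valid2
    num = np.where(both, num, 0.0)
    den = np.where(both, den, 0.0)
    return pi_case, pi_control, num, den, valid1, valid2, both


# ---------------------------------------------------------------------------
# sliding windows

def _window_layout(positions: np.ndarray, span: int, window: int, step: int):
    """Window starts plus (window-row, site-row) incidence for one chromosome.

    Windows are 0-based half-open [start, start+window) anchored at 0; a
    1-based position P belongs to a window iff P−1 falls in it.  The terminal
    window is truncated to the chromosome span and kept only if at least half
    a window wide.
    """
    starts = np.arange(0, max(span, 1), step, dtype=np.int64)
    widths = np.minimum(window, span - starts)
    keep = widths >= window / 2
    starts, widths = starts[keep], widths[keep]

    p0 = positions - 1
    n_off = int(np.ceil(window / step))
    widx, sidx = [], []
    site_rows = np.arange(len(positions))
    for off in range(n_off):
        j = p0 // step - off
        ok = (j >= 0) & (j < len(starts)) & (j * step + window > p0) & (p0 >= j * step)
        widx.append(j[ok])
        sidx.append(site_rows[ok])
    widx = np.concatenate(widx) if widx else np.empty(0, dtype=np.int64)
    sidx = np.concatenate(sidx) if sidx else np.empty(0, dtype=np.int64)
    return starts, widths, widx, sidx


def window_scan(
    matrix: GenotypeMatrix,
    window: int = 40_000,
    step: int = 20_000,
    min_sites: int = 10,
    estimator: str = "hudson",
    chrom_lengths: dict | None = None,
) -> pd.DataFrame:
    """Windowed FST, per-bp Pi and ΔPi over a sliding-window grid.

    Returns one row per retained window with columns (chrom, start, end,
    median_site, n_sites, fst, pi_case, pi_control, delta_pi), indexed by
    window id "chrom:start".  Pi is summed per-site diversity divided by the
    window width in bp; window FST is the ratio of summed Hudson (or
    Weir–Cockerham) components; ΔPi = pi_control − pi_case.  Sites lacking
    two called alleles in a population are excluded from that population's
    sums; ``n_sites`` counts sites usable for FST (both populations callable)
    and windows below ``min_sites`` are dropped.
    """
    case_cols = matrix.population_columns("case")
    control_cols = matrix.population_columns("control")
    pi1, pi2, num, den, v1, v2, both = _site_arrays(
        matrix, case_cols, control_cols, estimator
    )

    frames = []
    pos_all = matrix.sites["pos"].to_numpy()
    for chrom, grp in matrix.sites.groupby("chrom", sort=False):
        rows = grp.index.to_numpy()
        pos = pos_all[rows]
        span = int(chrom_lengths[chrom]) if chrom_lengths else int(pos.max())
        starts, widths, widx, sidx = _window_layout(pos, span, window, step)
        nw = len(starts)
        if nw == 0:
            continue
        sidx_g = rows[sidx]  # back to global site rows
        w_pi1 = np.bincount(widx, weights=pi1[sidx_g], minlength=nw)
        w_pi2 = np.bincount(widx, weights=pi2[sidx_g], minlength=nw)
        w_num = np.bincount(widx, weights=num[sidx_g], minlength=nw)
        w_den = np.bincount(widx, weights=den[sidx_g], minlength=nw)
        w_n = np.bincount(widx, weights=both[sidx_g].astype(float), minlength=nw)

        with np.errstate(divide="ignore", invalid="ignore"):
            fst = np.where(w_den != 0, w_num / np.where(w_den != 0, w_den, 1.0), 0.0)
        pi_case = w_pi1 / widths
        pi_control = w_pi2 / widths
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "start": starts,
                    "end": starts + widths,
                    "median_site": starts + window // 2,
                    "n_sites": w_n.astype(int),
                    "fst": fst,
                    "pi_case": pi_case,
                    "pi_control": pi_control,
                    "delta_pi": pi_control - pi_case,
                }
            )
        )
    if not frames:
        return pd.DataFrame(
            columns=["chrom", "start", "end", "median_site", "n_sites",
                     "fst", "pi_case", "pi_control", "delta_pi"]
        )
    out = pd.concat(frames, ignore_index=True)
    out = out[out["n_sites"] >= min_sites].reset_index(drop=True)
    out.index = pd.Index(
        out["chrom"].astype(str) + ":" + out["start"].astype(str), name="window"
    )
    return out


# ---------------------------------------------------------------------------
# candidate selection and recovery-ratio validation

def _top_set(values: pd.Series, q: float):
    """Ids of the top-⌈qn⌉ values; ties at the threshold value included."""
    n = len(values)
    if n == 0:
        return frozenset(), float("nan")
    k = max(1, int(np.ceil(q * n - 1e-9)))
    k = min(k, n)
    threshold = np.sort(values.to_numpy())[::-1][k - 1]
    return frozenset(values.index[values.to_numpy() >= threshold]), float(threshold)


def select_candidates(windows: pd.DataFrame, q: float = 0.01) -> CandidateSet:
    """Intersect the top-1% windows by descending FST and ΔPi.

    The threshold for each statistic is the k-th largest value with
    k = max(1, ⌈q·n⌉); a window enters a top set iff its value ≥ threshold
    (ties included).  Candidates are the intersection of the two top sets.
    """
    if len(windows) == 0:
        return CandidateSet(float("nan"), float("nan"), frozenset(), frozenset(),
                            windows.copy())
    top_fst, fst_thr = _top_set(windows["fst"], q)
    top_dpi, dpi_thr = _top_set(windows["delta_pi"], q)
    ids = sorted(top_fst & top_dpi, key=list(windows.index).index)
    table = windows.loc[ids, ["chrom", "start", "end", "fst", "delta_pi"]].copy()
    return CandidateSet(fst_thr, dpi_thr, top_fst, top_dpi, table)


def recovery_ratio(
    matrix: GenotypeMatrix,
    candidates: CandidateSet,
    n_replicates: int = 1000,
    subsample: int = 20,
    q: float = 0.01,
    seed: int = 0,
    window: int = 40_000,
    step: int = 20_000,
    min_sites: int = 10,
    estimator: str = "hudson",
    rr_min: float = 0.95,
    rule: str = "each",
    chrom_lengths: dict | None = None,
) -> CandidateSet:
    """Recovery ratio of each candidate under control subsampling.

    Each replicate draws ``subsample`` controls without replacement (the case
    set is unchanged), recomputes windowed FST and ΔPi, and re-derives the
    top-q sets.  rr_fst / rr_dpi are the fractions of replicates in which the
    candidate re-enters the FST / ΔPi top set, rr_joint the fraction in the
    intersection; each is a multiple of 1/n_replicates.  ``selected`` is
    rr_fst ≥ rr_min AND rr_dpi ≥ rr_min (``rule="each"``, default) or
    rr_joint ≥ rr_min (``rule="joint"``).  Replicate r uses the deterministic
    child seed (seed, r), so results do not depend on execution order.
    """
    if rule not in ("each", "joint"):
        raise ValueError(f"unknown rule: {rule!r}")
    case_cols = matrix.population_columns("case")
    control_cols = matrix.population_columns("control")
    pool = len(control_cols)
    if subsample > pool:
        raise ValueError(f"subsample {subsample} exceeds control pool {pool}")

    G = matrix.genotypes
    # fixed case-side per-site stats
    m1, a1 = _allele_stats(G, case_cols)
    Gc = G[:, control_cols]
    Gc_alt = np.where(Gc != MISSING, Gc, 0).astype(np.int32)
    Gc_called = (Gc != MISSING).astype(np.int32)
    Gc_het = (Gc == 1).astype(np.int32) if estimator == "wc84" else None

    # fixed window layout per chromosome (global window-row offsets)
    layouts = []
    offset = 0
    pos_all = matrix.sites["pos"].to_numpy()
    win_meta = []
    for chrom, grp in matrix.sites.groupby("chrom", sort=False):
        rows = grp.index.to_numpy()
        pos = pos_all[rows]
        span = int(chrom_lengths[chrom]) if chrom_lengths else int(pos.max())
        starts, widths, widx, sidx = _window_layout(pos, span, window, step)
        layouts.append((rows, widx + offset, sidx))
        for s, w in zip(starts, widths):
            win_meta.append((f"{chrom}:{s}", w))
        offset += len(starts)
    n_windows = offset
    win_ids = np.array([m[0] for m in win_meta])
    widths_all = np.array([m[1] for m in win_meta], dtype=float)
    widx_all = np.concatenate([lay[1] for lay in layouts])
    sidx_all = np.concatenate([lay[0][lay[2]] for lay in layouts])

    cand_ids = list(candidates.table.index)
    cand_rows = np.array([np.flatnonzero(win_ids == cid)[0] for cid in cand_ids]) \
        if cand_ids else np.empty(0, dtype=int)

    # case-side pi window sums are constant across replicates
    pi1_site = np.where(m1 >= 2, site_pi(a1, m1), 0.0)
    w_pi1 = np.bincount(widx_all, weights=pi1_site[sidx_all], minlength=n_windows)

    hits_fst = np.zeros(len(cand_ids), dtype=np.int64)
    hits_dpi = np.zeros(len(cand_ids), dtype=np.int64)
    hits_joint = np.zeros(len(cand_ids), dtype=np.int64)

    for r in range(n_replicates):
        rng = np.random.default_rng([seed, r])
        cols = rng.choice(pool, size=subsample, replace=False)
        m2 = 2 * Gc_called[:, cols].sum(axis=1)
        a2 = Gc_alt[:, cols].sum(axis=1)
        kwargs = {}
        if estimator == "wc84":
            with np.errstate(divide="ignore", invalid="ignore"):
                kwargs = {
                    "het1": np.where(m1 > 0, (G[:, case_cols] == 1).sum(axis=1)
                                     / np.maximum(m1 / 2, 1), 0.0),
                    "het2": np.where(m2 > 0, Gc_het[:, cols].sum(axis=1)
                                     / np.maximum(m2 / 2, 1), 0.0),
                }
        with np.errstate(divide="ignore", invalid="ignore"):
            p1 = np.where(m1 > 0, a1 / m1, 0.0)
            p2 = np.where(m2 > 0, a2 / m2, 0.0)
        num, den = site_fst(p1, np.maximum(m1, 2), p2, np.maximum(m2, 2),
                            estimator=estimator, **kwargs)
        both = (m1 >= 2) & (m2 >= 2)
        num = np.where(both, num, 0.0)
        den = np.where(both, den, 0.0)
        pi2_site = np.where(m2 >= 2, site_pi(a2, m2), 0.0)

        w_num = np.bincount(widx_all, weights=num[sidx_all], minlength=n_windows)
        w_den = np.bincount(widx_all, weights=den[sidx_all], minlength=n_windows)
        w_pi2 = np.bincount(widx_all, weights=pi2_site[sidx_all], minlength=n_windows)
        w_n = np.bincount(widx_all, weights=both[sidx_all].astype(float),
                          minlength=n_windows)

        keep = w_n >= min_sites
        with np.errstate(divide="ignore", invalid="ignore"):
            fst = np.where(w_den != 0, w_num / np.where(w_den != 0, w_den, 1.0), 0.0)
        dpi = (w_pi2 - w_pi1) / widths_all

        fst_s = pd.Series(fst[keep], index=win_ids[keep])
        dpi_s = pd.Series(dpi[keep], index=win_ids[keep])
        top_fst, _ = _top_set(fst_s, q)
        top_dpi, _ = _top_set(dpi_s, q)
        for i, cid in enumerate(cand_ids):
            in_f = cid in top_fst
            in_d = cid in top_dpi
            hits_fst[i] += in_f
            hits_dpi[i] += in_d
            hits_joint[i] += in_f and in_d

    table = candidates.table.copy()
    table["rr_fst"] = hits_fst / n_replicates
    table["rr_dpi"] = hits_dpi / n_replicates
    table["rr_joint"] = hits_joint / n_replicates
    if rule == "each":
        table["selected"] = (table["rr_fst"] >= rr_min) & (table["rr_dpi"] >= rr_min)
    else:
        table["selected"] = table["rr_joint"] >= rr_min
    return CandidateSet(
        candidates.fst_threshold,
        candidates.dpi_threshold,
        candidates.top_fst,
        candidates.top_dpi,
        table,
        n_replicates=n_replicates,
        rr_min=rr_min,
    )


# ---------------------------------------------------------------------------
# genotype-frequency (GF) filter

def differentiated_sites(
    matrix: GenotypeMatrix,
    min_case_called: int = 16,
    min_control_called: int = 51,
    case_ratio_gt: float = 0.8,
    control_ratio_lt: float = 0.06,
    mode: str = "allele",
) -> pd.DataFrame:
    """Highly differentiated SNPs/indels by the genotype-frequency rule.

    A site is *eligible* iff it is called in at least ``min_case_called``
    cases and ``min_control_called`` controls (the defaults encode the strict
    "more than 15 of 20 cases / more than 50 of 98 controls" rule).  For an
    eligible site the altered-allele ratio must exceed ``case_ratio_gt`` in
    cases and fall below ``control_ratio_lt`` in controls (strict
    inequalities).  ``mode="allele"`` uses the alt-allele frequency among
    called alleles, (het + 2·hom-alt)/(2·n_called); ``mode="carrier"`` uses
    the fraction of called individuals carrying at least one alt allele.
    SNPs and indels are treated identically and reported with their type.
    """
    if mode not in ("allele", "carrier"):
        raise ValueError(f"unknown mode: {mode!r}")
    case_cols = matrix.population_columns("case")
    control_cols = matrix.population_columns("control")

    def stats(cols):
        sub = matrix.genotypes[:, cols]
        called = (sub != MISSING).sum(axis=1)
        if mode == "allele":
            numer = np.where(sub != MISSING, sub, 0).sum(axis=1).astype(float)
            denom = 2.0 * called
        else:
            numer = (sub >= 1).sum(axis=1).astype(float)
            denom = called.astype(float)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(denom > 0, numer / np.maximum(denom, 1), 0.0)
        return called, ratio

    case_called, case_ratio = stats(case_cols)
    control_called, control_ratio = stats(control_cols)
    eligible = (case_called >= min_case_called) & (control_called >= min_control_called)
    passed = eligible & (case_ratio > case_ratio_gt) & (control_ratio < control_ratio_lt)

    out = matrix.sites[["chrom", "pos", "ref", "alt", "site_type"]].copy()
    out["case_called"] = case_called
    out["control_called"] = control_called
    out["case_ratio"] = case_ratio
    out["control_ratio"] = control_ratio
    out["eligible"] = eligible
    out["passed"] = passed
    out.index = pd.Index(matrix.site_ids(), name="site")
    return out
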