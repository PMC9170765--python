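"""Synthetic genotype and expression data with planted, recoverable truth.

The genotype simulator emulates the 20-case / 98-control re-sequencing design:
Balding–Nichols background divergence, planted sweep regions (case allele
frequencies displaced toward fixation, which jointly raises FST and lowers
case diversity) and planted highly differentiated sites that satisfy the
genotype-frequency filter by construction.  The expression simulator emulates
the 21-embryo RNA-seq design (9 case / 12 control over three developmental
days, two control breeds, several lanes) with planted differentially
expressed genes and planted correlated gene modules, emitting nested counts
from the two HTSeq-style counting models.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genoscan import MISSING, GenotypeMatrix

__all__ = [
    "GenoSimConfig",
    "ExprSimConfig",
    "Truth",
    "simulate_genotypes",
    "simulate_expression",
    "write_vcf",
    "write_panel",
]

_BASES = np.array(list("ACGT"))


@dataclass
class Truth:
    """Ground truth emitted alongside a simulated dataset.

    Window ids are "chrom:start" strings matching :func:`genoscan.window_scan`
    indices; site ids are "chrom:pos"; module assignment maps gene id to a
    planted module label.
    """

    sweep_window_ids: set = field(default_factory=set)
    diff_site_ids: set = field(default_factory=set)
    de_gene_ids: set = field(default_factory=set)
    module_assignment: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        payload = {
            "sweep_window_ids": sorted(self.sweep_window_ids),
            "diff_site_ids": sorted(self.diff_site_ids),
            "de_gene_ids": sorted(self.de_gene_ids),
            "module_assignment": self.module_assignment,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)


# ---------------------------------------------------------------------------
# genotype simulation

@dataclass
class GenoSimConfig:
    """Parameters of the genotype simulator.

    Defaults give 5 chromosomes of 2 Mb at one variant per ~200 bp
    (≈ 500 windows of 40 kb stepped by 20 kb), background FST 0.05, one
    grid-aligned 40-kb sweep per chromosome with a 0.6 frequency shift, and
    25 planted highly differentiated sites.
    """

    n_case: int = 20
    n_control: int = 98
    n_chrom: int = 5
    chrom_length: int = 2_000_000
    site_density: float = 0.005
    background_fst: float = 0.05
    sweep_regions: list | None = None  # [(chrom, start, end)], 0-based half-open
    sweep_shift: float = 0.6
    diff_site_count: int = 25
    indel_fraction: float = 0.1
    missing_rate: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.background_fst < 1:
            raise ValueError("background_fst must be in [0, 1)")
        if not 0 <= self.missing_rate < 0.5:
            raise ValueError("missing_rate must be in [0, 0.5)")
        if not 0 <= self.sweep_shift <= 1:
            raise ValueError("sweep_shift must be in [0, 1]")
        if self.sweep_regions is None:
            # one 40-kb region per chromosome, aligned to the 20-kb grid;
            # chromosomes too short for a full window get no sweep
            mid = (self.chrom_length // 2 // 20_000) * 20_000
            if mid + 40_000 <= self.chrom_length:
                self.sweep_regions = [
                    (f"chr{i + 1}", mid, mid + 40_000)
                    for i in range(self.n_chrom)
                ]
            else:
                self.sweep_regions = []
        chroms = {f"chr{i + 1}" for i in range(self.n_chrom)}
        by_chrom: dict[str, list] = {}
        for region in self.sweep_regions:
            chrom, start, end = region
            if chrom not in chroms or start < 0 or end > self.chrom_length or start >= end:
                raise ValueError(f"sweep region outside chromosome bounds: {region}")
            by_chrom.setdefault(chrom, []).append((start, end))
        for chrom, regs in by_chrom.items():
            regs.sort()
            for (s1, e1), (s2, e2) in zip(regs, regs[1:]):
                if s2 < e1:
                    raise ValueError(
                        f"overlapping sweep regions on {chrom}: "
                        f"({s1}, {e1}) and ({s2}, {e2})"
                    )


def _balding_nichols(rng, p0: np.ndarray, fst: float) -> np.ndarray:
    """Population allele frequencies given ancestral p0 under divergence F."""
    if fst == 0:
        return p0.copy()
    a = p0 * (1 - fst) / fst
    b = (1 - p0) * (1 - fst) / fst
    return rng.beta(a, b)


def simulate_genotypes(config: GenoSimConfig) -> tuple[GenotypeMatrix, Truth]:
    """Draw a biallelic case/control genotype matrix with planted signals.

    Sites are Poisson-spaced; each has an ancestral frequency
    p0 ~ Uniform(0.05, 0.95) and per-population frequencies drawn
    independently from Balding–Nichols Beta(p0(1−F)/F, (1−p0)(1−F)/F).
    Inside sweep regions the case frequency is additionally displaced by
    ``sweep_shift`` toward the nearer of {0, 1} (truncated).  Planted
    differentiated sites are written as hom-alt in every case and hom-ref in
    every control before missingness, so they pass the GF filter whenever
    ``missing_rate`` leaves enough calls (always at missing_rate = 0).
    Genotypes are Binomial(2, population frequency) and missingness is i.i.d.
    The same seed and config reproduce the output bitwise.
    """
    rng = np.random.default_rng(config.seed)
    n_case, n_ctrl = config.n_case, config.n_control
    frames, geno_blocks = [], []
    truth = Truth()

    regions_by_chrom: dict[str, list] = {}
    for chrom, start, end in config.sweep_regions:
        regions_by_chrom.setdefault(chrom, []).append((start, end))

    for ci in range(config.n_chrom):
        chrom = f"chr{ci + 1}"
        n_expect = int(config.chrom_length * config.site_density * 1.2) + 10
        gaps = rng.exponential(scale=1.0 / config.site_density, size=n_expect)
        pos = np.unique(np.ceil(np.cumsum(gaps)).astype(np.int64))
        pos = pos[(pos >= 1) & (pos <= config.chrom_length)]
        n_sites = len(pos)

        p0 = rng.uniform(0.05, 0.95, size=n_sites)
        p_case = _balding_nichols(rng, p0, config.background_fst)
        p_ctrl = _balding_nichols(rng, p0, config.background_fst)

        in_sweep = np.zeros(n_sites, dtype=bool)
        for start, end in regions_by_chrom.get(chrom, []):
            in_sweep |= (pos - 1 >= start) & (pos - 1 < end)
        if config.sweep_shift > 0 and in_sweep.any():
            p = p_case[in_sweep]
            shifted = np.where(
                p >= 0.5,
                np.minimum(1.0, p + config.sweep_shift),
                np.maximum(0.0, p - config.sweep_shift),
            )
            p_case[in_sweep] = shifted

        g_case = rng.binomial(2, p_case[:, None], size=(n_sites, n_case))
        g_ctrl = rng.binomial(2, p_ctrl[:, None], size=(n_sites, n_ctrl))

        ref = rng.choice(_BASES, size=n_sites)
        alt_shift = rng.integers(1, 4, size=n_sites)
        ref_idx = np.searchsorted(_BASES, ref)
        alt = _BASES[(ref_idx + alt_shift) % 4]
        is_indel = rng.random(n_sites) < config.indel_fraction
        ins = rng.choice(_BASES, size=n_sites)
        alt = np.where(is_indel, np.char.add(ref.astype(object), ins.astype(object)), alt)
        site_type = np.where(is_indel, "indel", "SNP")

        frames.append(
            pd.DataFrame(
                {"chrom": chrom, "pos": pos, "ref": ref, "alt": alt,
                 "site_type": site_type}
            )
        )
        geno_blocks.append(
            (np.concatenate([g_case, g_ctrl], axis=1).astype(np.int8), in_sweep)
        )

        for start, end in regions_by_chrom.get(chrom, []):
            w = start // 20_000 * 20_000
            while w + 40_000 <= end:
                if w >= start:
                    truth.sweep_window_ids.add(f"{chrom}:{w}")
                w += 20_000

    sites = pd.concat(frames, ignore_index=True)
    genotypes = np.concatenate([b[0] for b in geno_blocks], axis=0)
    in_sweep_all = np.concatenate([b[1] for b in geno_blocks])

    # plant differentiated sites outside sweep regions: all cases hom-alt,
    # all controls hom-ref — maximally separated genotype frequencies
    eligible_rows = np.flatnonzero(~in_sweep_all)
    if config.diff_site_count > len(eligible_rows):
        raise ValueError("diff_site_count exceeds available non-sweep sites")
    planted = rng.choice(eligible_rows, size=config.diff_site_count, replace=False)
    genotypes[planted, :n_case] = 2
    genotypes[planted, n_case:] = 0
    for row in planted:
        truth.diff_site_ids.add(f"{sites.at[row, 'chrom']}:{sites.at[row, 'pos']}")

    if config.missing_rate > 0:
        miss = rng.random(genotypes.shape) < config.missing_rate
        genotypes[miss] = MISSING

    panel = pd.DataFrame(
        {
            "population": ["case"] * n_case + ["control"] * n_ctrl,
            "subgroup": ["Piao"] * n_case + ["control"] * n_ctrl,
        },
        index=pd.Index(
            [f"P{i + 1:03d}" for i in range(n_case)]
            + [f"C{i + 1:03d}" for i in range(n_ctrl)],
            name="sample_id",
        ),
    )
    return GenotypeMatrix(sites, genotypes, panel), truth


# ---------------------------------------------------------------------------
# VCF / panel output

_GT_STR = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(matrix: GenotypeMatrix, path) -> None:
    """Write a minimal VCF 4.2 with GT fields; round-trips through read_vcf."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in matrix.sites["chrom"].unique():
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(matrix.panel.index)
            + "\n"
        )
        sites = matrix.sites
        for row in range(len(sites)):
            gts = "\t".join(_GT_STR[int(g)] for g in matrix.genotypes[row])
            fh.write(
                f"{sites.at[row, 'chrom']}\t{sites.at[row, 'pos']}\t.\t"
                f"{sites.at[row, 'ref']}\t{sites.at[row, 'alt']}\t.\tPASS\t.\tGT\t{gts}\n"
            )


def write_panel(matrix: GenotypeMatrix, path) -> None:
    matrix.panel.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# expression simulation

@dataclass
class ExprSimConfig:
    """Parameters of the expression simulator.

    Defaults follow the embryo RNA-seq design: 9 case samples (3 per
    developmental day) and 12 controls (2 breeds × 3 days × 2 replicates),
    sequenced over 3 lanes.  ``covariate_effects`` are log2-scale standard
    deviations of per-gene covariate coefficients; ``module_cor`` is the
    latent-factor loading λ of planted modules (pairwise expression
    correlation ≈ λ² on the latent scale); ``dispersion`` is the
    negative-binomial α in Var = μ + αμ².
    """

    n_case: int = 9
    n_control: int = 12
    days: int = 3
    control_breeds: int = 2
    lanes: int = 3
    n_genes: int = 2000
    n_de: int = 100
    de_log2fc: float = 2.0
    module_sizes: tuple = ()
    module_cor: float = 0.95
    module_amplitude: float = 2.0
    dispersion: float = 0.05
    covariate_effects: dict | None = None
    noise_sd: float = 0.5
    baseline_log2_mean: float = 5.0
    baseline_log2_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.covariate_effects is None:
            self.covariate_effects = {"day": 0.2, "breed": 0.3, "lane": 0.1}
        if sum(self.module_sizes) > self.n_genes:
            raise ValueError("sum(module_sizes) exceeds n_genes")
        if self.n_de > self.n_genes:
            raise ValueError("n_de exceeds n_genes")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        if not 0 < self.module_cor < 1:
            raise ValueError("module_cor must be in (0, 1)")


def _sample_table(config: ExprSimConfig) -> pd.DataFrame:
    days = [f"D{7 + d}" for d in range(config.days)]
    rows = []
    for i in range(config.n_case):
        rows.append((f"P{i + 1:02d}", "case", days[i % config.days], "Piao"))
    breeds = ["Gushi", "Wuding"][: config.control_breeds] or ["Gushi"]
    per_breed = config.n_control // len(breeds)
    k = 0
    for b, breed in enumerate(breeds):
        n_b = per_breed + (1 if b < config.n_control % len(breeds) else 0)
        for i in range(n_b):
            rows.append((f"C{k + 1:02d}", "control", days[i % config.days], breed))
            k += 1
    meta = pd.DataFrame(rows, columns=["sample_id", "group", "day", "breed"])
    # staggered (Latin-square) lane assignment so lanes cut across days and
    # breeds instead of aliasing the day rotation
    meta["lane"] = [f"L{(i + i // config.days) % config.lanes + 1}"
                    for i in range(len(meta))]
    return meta.set_index("sample_id")


def simulate_expression(config: ExprSimConfig):
    """Draw nested NB count matrices with planted DE genes and modules.

    The log2 expected count of gene g in sample s is
    baseline_g + group effect (±de_log2fc for DE genes in cases)
    + day slope·day code + breed/lane coefficients + module latent signal.
    The breed term is a contrast between the two control breeds (case
    samples sit at the reference level): a whole-breed case effect would be
    indistinguishable from the group effect in this design, so it is
    deliberately absent and the group coefficient stays identifiable.
    counts_union is NB(μ, α); counts_whole adds Poisson "intronic" reads on
    top, so whole-gene counts dominate union-exon counts elementwise.
    FPKM is computed exactly from counts_union, simulated gene lengths
    (LogUniform 200–10⁵ bp) and per-sample totals.
    """
    from .degflow import ExpressionSet, compute_fpkm

    rng = np.random.default_rng(config.seed)
    meta = _sample_table(config)
    n_s = len(meta)
    genes = pd.Index([f"G{i + 1:05d}" for i in range(config.n_genes)], name="gene")
    truth = Truth()

    baseline = rng.normal(config.baseline_log2_mean, config.baseline_log2_sd,
                          size=config.n_genes)
    log2mu = np.tile(baseline[:, None], (1, n_s))

    day_code = meta["day"].str.removeprefix("D").astype(int) - 6  # D7→1, D8→2, D9→3
    eff = config.covariate_effects
    day_slope = rng.normal(0.0, eff.get("day", 0.0), size=config.n_genes)
    log2mu += day_slope[:, None] * day_code.to_numpy()[None, :]

    breeds = [b for b in meta["breed"].unique() if b != "Piao"]
    if len(breeds) > 1:  # contrast among control breeds, first as reference
        for breed in breeds[1:]:
            coef = rng.normal(0.0, eff.get("breed", 0.0), size=config.n_genes)
            log2mu += coef[:, None] * (meta["breed"] == breed).to_numpy()[None, :]
    lanes = sorted(meta["lane"].unique())
    for lane in lanes[1:]:
        coef = rng.normal(0.0, eff.get("lane", 0.0), size=config.n_genes)
        log2mu += coef[:, None] * (meta["lane"] == lane).to_numpy()[None, :]

    # planted DE genes: group shift of ±de_log2fc applied to case samples
    de_rows = rng.choice(config.n_genes, size=config.n_de, replace=False) \
        if config.n_de else np.empty(0, dtype=int)
    signs = rng.choice([-1.0, 1.0], size=len(de_rows))
    is_case = (meta["group"] == "case").to_numpy()
    for row, s in zip(de_rows, signs):
        log2mu[row, is_case] += s * config.de_log2fc
        truth.de_gene_ids.add(genes[row])

    # planted co-expression modules on non-DE genes: latent factor per module
    lam = config.module_cor
    non_de = np.setdiff1d(np.arange(config.n_genes), de_rows)
    if sum(config.module_sizes) > len(non_de):
        raise ValueError("module_sizes leave no room beside DE genes")
    pool = rng.permutation(non_de)
    signal = config.noise_sd * rng.normal(0.0, 1.0, size=(config.n_genes, n_s))
    used = 0
    for k, size in enumerate(config.module_sizes):
        members = pool[used:used + size]
        used += size
        factor = rng.normal(0.0, 1.0, size=n_s)
        eps = rng.normal(0.0, 1.0, size=(size, n_s))
        # module genes share a latent program of amplitude module_amplitude
        # (log2 units); loading λ sets the shared fraction λ² of its variance
        signal[members] = config.module_amplitude * (
            lam * factor[None, :] + np.sqrt(1 - lam**2) * eps
        )
        for row in members:
            truth.module_assignment[genes[row]] = f"M{k + 1}"
    log2mu += signal

    # per-sample sequencing depth scales every gene's expected count and is
    # divided back out by FPKM normalization
    depth = rng.normal(0.0, 0.15, size=n_s)
    log2mu += depth[None, :]

    mu = np.exp2(np.clip(log2mu, -2, 22))
    n_param = 1.0 / config.dispersion
    counts_union = rng.negative_binomial(n_param, n_param / (n_param + mu))
    counts_whole = counts_union + rng.poisson(0.05 * mu)

    length = np.exp(rng.uniform(np.log(200.0), np.log(1e5), size=config.n_genes))
    gene_meta = pd.DataFrame(
        {"length": np.round(length).astype(int), "gc": rng.uniform(0.3, 0.7, config.n_genes)},
        index=genes,
    )
    cu = pd.DataFrame(counts_union, index=genes, columns=meta.index)
    cw = pd.DataFrame(counts_whole, index=genes, columns=meta.index)
    # the simulated panel is a small subsample of the transcriptome, so the
    # mapped-fragment total is the nominal transcriptome depth (scaled by
    # the same per-sample depth factor as the counts) rather than the panel
    # column sum, which a handful of high-amplitude genes would dominate at
    # desk scale
    lib_size = pd.Series(
        np.round(1e6 * np.exp2(depth)).astype(int), index=meta.index,
    )
    fpkm = compute_fpkm(cu, gene_meta["length"], lib_size)
    eset = ExpressionSet(cu, cw, fpkm, gene_meta, meta.copy(), lib_size)
    return eset, truth
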