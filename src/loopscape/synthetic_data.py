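"""Synthetic cohorts with the statistical structure the pipeline assumes.

The generator emulates, at desk scale, the data structure of a two-cell-type
T-cell cohort profiled by Hi-C, RNA-seq and ATAC-seq:

* contact maps with power-law distance decay ``P(d) ~ (d + d0)^-alpha``,
  block-enriched TADs and focal loop enrichments on 3x3 pixel neighbourhoods
  at 5 kb, with Poisson pixel counts;
* biallelic genotypes drawn Binomial(2, MAF) per sample;
* loop-strength, expression and accessibility phenotypes with a linear
  genotype effect on the latent (log2) scale, a cell-type group effect on a
  configurable fraction of features, and a binary sex covariate shifting a
  fraction of features;
* allele-specific counts that are beta-binomially overdispersed around a
  shared allelic log-odds theta for heterozygous carriers.

Every generator is a pure function of (config, seed); the injected effects
are returned as ground-truth tables so estimator recovery can be tested.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.special import expit

from . import core_io
from .core_io import ContactMatrix, GenomicInterval, GenotypeMatrix, Loop, SampleMetadata


@dataclass
class SimulationConfig:
    """Parameters of the synthetic cohort; defaults mirror the study design.

    The cohort defaults to 40 samples split evenly into two T-cell types
    with a balanced binary sex covariate.  Loop phenotypes live on a latent
    log2 scale with unit noise; a group effect of ``group_effect_size``
    (in units of ``noise_sd``) is injected into ``group_effect_fraction`` of
    features.  ``qtl_effects`` are per-alt-allele slopes on the latent scale;
    ``imbalance_effects`` are allelic log-odds.
    """

    seed: int
    n_samples: int = 40
    cell_types: tuple[str, str] = ("CD4", "CD8")

    # contact-map generator
    chrom: str = "chr1"
    chrom_length: int = 1_000_000
    resolution: int = 5_000
    depth: float = 500_000.0
    decay_exponent: float = 1.0
    tad_blocks: list[tuple[GenomicInterval, float]] = dc_field(default_factory=list)
    loops: list[tuple[Loop, float]] = dc_field(default_factory=list)
    make_contact_maps: bool = False

    # phenotype generator
    n_loop_features: int = 2_000
    n_genes: int = 500
    n_peaks: int = 500
    feature_spacing: int = 25_000
    baseline_log2: float = 5.0
    noise_sd: float = 1.0
    group_effect_fraction: float = 0.1
    group_effect_size: float = 0.5
    sex_effect_fraction: float = 0.05
    sex_effect_size: float = 0.5
    nb_dispersion: float = 0.1

    # genotypes
    n_variants: int = 50
    maf: float = 0.3
    qtl_effects: list[tuple[int, str, float]] = dc_field(default_factory=list)

    # allele-specific counts
    imbalance_effects: list[tuple[int, float]] = dc_field(default_factory=list)
    allele_depth: float = 100.0
    overdispersion: float = 0.02

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.decay_exponent <= 0:
            raise ValueError("decay_exponent must be positive")
        if not (0 <= self.overdispersion < 0.5):
            raise ValueError("overdispersion must lie in [0, 0.5)")
        if not (0 < self.maf <= 0.5):
            raise ValueError("MAF must lie in (0, 0.5]")


@dataclass
class SyntheticCohort:
    config: SimulationConfig
    metadata: SampleMetadata
    genotypes: GenotypeMatrix
    loop_features: list[Loop]
    loop_strengths: pd.DataFrame  # latent log2 loop strengths, loops x samples
    expression: pd.DataFrame  # raw counts, genes x samples
    accessibility: pd.DataFrame  # raw counts, peaks x samples
    gene_tss: dict[str, int]
    peak_intervals: list[GenomicInterval]
    allele_counts: pd.DataFrame  # sample, variant, ref_count, alt_count
    contact_matrices: dict[str, ContactMatrix] | None
    truth: dict[str, pd.DataFrame]

    @property
    def samples(self) -> list[str]:
        return self.metadata.sample_ids


# ---------------------------------------------------------------------------
# contact maps
# ---------------------------------------------------------------------------

def expected_pixel_means(config: SimulationConfig) -> np.ndarray:
    """Dense matrix of expected (Poisson-mean) contact counts for one library.

    mean(i, j) = depth-scaled (d + d0)^-alpha, times the TAD enrichment when
    both bins fall in a TAD block, times the loop fold on the loop's 3x3
    pixel neighbourhood.  d0 is one bin, avoiding the d = 0 singularity.
    """
    res = config.resolution
    n = -(-config.chrom_length // res)
    d = np.abs(np.subtract.outer(np.arange(n), np.arange(n))) * res
    base = (d + res) ** (-config.decay_exponent)
    for block, fold in config.tad_blocks:
        b0, b1 = block.start // res, -(-block.end // res)
        inside = np.zeros(n, dtype=bool)
        inside[b0:b1] = True
        base[np.ix_(inside, inside)] *= fold
    for loop, fold in config.loops:
        if loop.anchor2.end > config.chrom_length:
            raise ValueError(f"loop {loop.id} outside the chromosome")
        ci = loop.anchor1.midpoint // res
        cj = loop.anchor2.midpoint // res
        base[max(0, ci - 1) : ci + 2, max(0, cj - 1) : cj + 2] *= fold
        base[max(0, cj - 1) : cj + 2, max(0, ci - 1) : ci + 2] *= fold
    # scale the upper triangle (incl. diagonal) to the target depth
    upper_sum = np.triu(base).sum()
    return base * (config.depth / upper_sum)


def simulate_contact_map(
    config: SimulationConfig, depth_multiplier: float = 1.0, seed: int | None = None
) -> ContactMatrix:
    """One library's contact matrix: Poisson counts around the expected means."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    mean = expected_pixel_means(config) * depth_multiplier
    n = mean.shape[0]
    upper = np.triu(rng.poisson(mean).astype(float))
    return ContactMatrix(
        chrom=config.chrom,
        resolution=config.resolution,
        n_bins=n,
        counts=sp.csr_matrix(np.triu(upper)),
    )


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------

def _feature_loop(k: int, chrom: str, spacing: int) -> Loop:
    start = 10_000 + k * spacing
    return Loop(
        f"loop_{k:05d}",
        GenomicInterval(chrom, start, start + 5_000),
        GenomicInterval(chrom, start + 100_000, start + 105_000),
    )


def simulate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Draw a full synthetic cohort plus the ground-truth effect tables.

    Genotypes are Binomial(2, MAF) per sample.  Each phenotype's latent
    value is ``baseline + group effect + sex effect + qtl slope * dosage +
    Normal(0, noise_sd)``; count phenotypes (expression, accessibility) are
    negative-binomially sampled around ``2**latent``.  Allele-specific alt
    counts are BetaBinomial(n, logistic(theta), phi) for heterozygous
    carriers of each imbalance variant.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_samples
    samples = [f"S{k:03d}" for k in range(n)]
    cell_type = np.array(
        [config.cell_types[0]] * (n - n // 2) + [config.cell_types[1]] * (n // 2)
    )
    sex = rng.integers(0, 2, size=n)
    meta = SampleMetadata(
        pd.DataFrame(
            {"cell_type": cell_type, "condition": "none", "sex": sex},
            index=pd.Index(samples, name="sample_id"),
        )
    )

    # --- genotypes: variants placed at loop-feature midspans, cycling ---
    chrom = config.chrom
    spacing = config.feature_spacing
    dosages = rng.binomial(2, config.maf, size=(config.n_variants, n)).astype(float)
    var_pos = [15_000 + (k * 7 % max(config.n_loop_features, 1)) * spacing
               for k in range(config.n_variants)]
    variants = pd.DataFrame(
        {
            "id": [f"var_{k:04d}" for k in range(config.n_variants)],
            "chrom": chrom,
            "pos": var_pos,
            "ref": "A",
            "alt": "G",
        }
    )
    genotypes = GenotypeMatrix(variants=variants, samples=samples, dosages=dosages)

    group_ind = (cell_type == config.cell_types[1]).astype(float)
    truth: dict[str, pd.DataFrame] = {}

    def _latent_block(feature_ids: list[str], prefix: str) -> tuple[np.ndarray, pd.DataFrame]:
        m = len(feature_ids)
        n_group = int(round(config.group_effect_fraction * m))
        n_sex = int(round(config.sex_effect_fraction * m))
        group_feats = rng.choice(m, size=n_group, replace=False) if n_group else np.array([], int)
        sex_feats = rng.choice(m, size=n_sex, replace=False) if n_sex else np.array([], int)
        latent = np.full((m, n), config.baseline_log2)
        g_eff = config.group_effect_size * config.noise_sd
        s_eff = config.sex_effect_size * config.noise_sd
        latent[group_feats] += g_eff * group_ind
        latent[sex_feats] += s_eff * sex
        slopes = np.zeros(m)
        for var_idx, fid, slope in config.qtl_effects:
            if fid in feature_ids:
                fi = feature_ids.index(fid)
                latent[fi] += slope * dosages[var_idx]
                slopes[fi] = slope
        latent += rng.normal(0, config.noise_sd, size=(m, n))
        tt = pd.DataFrame(
            {
                "feature_id": feature_ids,
                "group_effect": [g_eff if k in set(group_feats) else 0.0 for k in range(m)],
                "sex_effect": [s_eff if k in set(sex_feats) else 0.0 for k in range(m)],
                "qtl_slope": slopes,
            }
        )
        return latent, tt

    # --- loop strengths (latent log2 scale, continuous) ---
    loop_feats = [_feature_loop(k, chrom, spacing) for k in range(config.n_loop_features)]
    loop_ids = [lp.id for lp in loop_feats]
    loop_latent, truth["loops"] = _latent_block(loop_ids, "loop")
    loop_strengths = pd.DataFrame(loop_latent, index=loop_ids, columns=samples)

    # --- expression / accessibility (NB counts around 2**latent) ---
    def _nb_counts(latent: np.ndarray) -> np.ndarray:
        mu = 2.0**latent
        if config.nb_dispersion <= 0:
            return rng.poisson(mu).astype(float)
        size = 1.0 / config.nb_dispersion
        lam = rng.gamma(shape=size, scale=mu / size)
        return rng.poisson(lam).astype(float)

    gene_ids = [f"gene_{k:04d}" for k in range(config.n_genes)]
    gene_latent, truth["genes"] = _latent_block(gene_ids, "gene")
    expression = pd.DataFrame(_nb_counts(gene_latent), index=gene_ids, columns=samples)
    gene_tss = {gid: 12_500 + k * spacing for k, gid in enumerate(gene_ids)}

    peak_ids = [f"peak_{k:04d}" for k in range(config.n_peaks)]
    peak_latent, truth["peaks"] = _latent_block(peak_ids, "peak")
    accessibility = pd.DataFrame(_nb_counts(peak_latent), index=peak_ids, columns=samples)
    peak_intervals = [
        GenomicInterval(chrom, 12_250 + k * spacing, 12_750 + k * spacing)
        for k in range(config.n_peaks)
    ]

    # --- allele-specific counts for heterozygous carriers ---
    ac_rows = []
    imb_truth = []
    for var_idx, theta in config.imbalance_effects:
        p_alt = expit(theta)
        phi = max(config.overdispersion, 0.0)
        het = np.flatnonzero(dosages[var_idx] == 1)
        for s_idx in het:
            depth = max(int(rng.poisson(config.allele_depth)), 1)
            if phi > 0:
                a = p_alt * (1 - phi) / phi
                b = (1 - p_alt) * (1 - phi) / phi
                p_i = rng.beta(a, b)
            else:
                p_i = p_alt
            alt = int(rng.binomial(depth, p_i))
            ac_rows.append(
                {
                    "sample": samples[s_idx],
                    "variant": variants["id"][var_idx],
                    "ref_count": depth - alt,
                    "alt_count": alt,
                }
            )
        imb_truth.append(
            {"variant": variants["id"][var_idx], "theta": theta, "n_het": len(het)}
        )
    allele_counts = pd.DataFrame(
        ac_rows, columns=["sample", "variant", "ref_count", "alt_count"]
    )
    truth["imbalance"] = pd.DataFrame(
        imb_truth, columns=["variant", "theta", "n_het"]
    )

    # --- optional per-sample contact maps ---
    contact_matrices = None
    if config.make_contact_maps:
        contact_matrices = {
            s: simulate_contact_map(
                config, seed=int(rng.integers(0, 2**31 - 1))
            )
            for s in samples
        }

    return SyntheticCohort(
        config=config,
        metadata=meta,
        genotypes=genotypes,
        loop_features=loop_feats,
        loop_strengths=loop_strengths,
        expression=expression,
        accessibility=accessibility,
        gene_tss=gene_tss,
        peak_intervals=peak_intervals,
        allele_counts=allele_counts,
        contact_matrices=contact_matrices,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# fixture bundles
# ---------------------------------------------------------------------------

def write_fixture_bundle(cohort: SyntheticCohort, out_dir: str | Path) -> pd.DataFrame:
    """Write the cohort to plain-text files; returns a checksum manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    core_io.write_bedpe(cohort.loop_features, out / "loops.bedpe")
    core_io.write_bed(cohort.peak_intervals, out / "peaks.bed",
                      names=list(cohort.accessibility.index))
    with open(out / "tss.tsv", "w") as fh:
        for gid, tss in cohort.gene_tss.items():
            fh.write(f"{cohort.config.chrom}\t{tss}\t{tss + 1}\t{gid}\n")
    core_io.write_vcf(cohort.genotypes, out / "genotypes.vcf")
    core_io.write_feature_table(cohort.loop_strengths, out / "loop_strengths.tsv")
    core_io.write_feature_table(cohort.expression, out / "expression.tsv")
    core_io.write_feature_table(cohort.accessibility, out / "accessibility.tsv")
    cohort.allele_counts.to_csv(out / "allele_counts.tsv", sep="\t", index=False)
    cohort.metadata.table.to_csv(out / "samples.tsv", sep="\t")
    for name, table in cohort.truth.items():
        table.to_csv(out / f"truth_{name}.tsv", sep="\t", index=False)
    if cohort.contact_matrices:
        for s, m in cohort.contact_matrices.items():
            core_io.write_contact_matrix(m, out / f"contacts_{s}.tsv")

    rows = []
    for f in sorted(out.iterdir()):
        if f.name == "MANIFEST.tsv":
            continue
        digest = hashlib.sha256(f.read_bytes()).hexdigest()
        rows.append({"file": f.name, "sha256": digest})
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out / "MANIFEST.tsv", sep="\t", index=False)
    return manifest
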