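"""Synthetic GWAS summary statistics with known ground truth.

Two generators cover the pipeline's inputs:

* :func:`simulate_mr_study` draws a two-sample MR dataset: per-SNP
  exposure effects gamma_j, direct (pleiotropic) outcome effects
  alpha_j, latent outcome effects ``b * gamma_j + alpha_j``, and
  observed estimates with sampling noise whose SE follows the standard
  marginal-GWAS approximation ``se ~ 1/sqrt(2 MAF (1-MAF) N)``, so
  instrument-strength F statistics and power analyses are internally
  consistent with the stated sample sizes.
* :func:`simulate_lookup_study` plants well-separated loci of catalog
  SNPs and per-phenotype summary statistics with designated significant
  members and known effect directions, so the look-up pipeline's
  clustering, lead-SNP selection and concordance tabulation can be
  checked against the planted truth.

Defaults mirror a two-sample design of 328 instruments from a
694,649-individual exposure GWAS looked up in a 105,318-individual
case-control outcome GWAS (38.6% cases), with instrument strengths
giving a mean per-SNP F near 86 and 9/328 palindromic allele pairs.
Pleiotropy is drawn independently of instrument strength (InSIDE holds)
unless ``inside_violated`` is set.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from crossmr.sumstats_io import SUMSTAT_COLUMNS, CATALOG_COLUMNS
from scipy import stats

_NONPALINDROMIC_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
                         ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T")]
_PALINDROMIC_PAIRS = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]


@dataclass
class SyntheticMRConfig:
    """Generative parameters for a two-sample MR dataset."""

    n_snps: int = 328
    true_beta: float = 0.0
    gamma_mean: float = 0.0172     # exposure effect size (trait-SD units)
    gamma_sd: float = 0.0065
    pleio_mean: float = 0.0        # directional pleiotropy when != 0
    pleio_sd: float = 0.0
    n_exposure: int = 694_649
    n_outcome: int = 105_318
    case_fraction: float | None = 40_675 / 105_318
    maf_range: tuple[float, float] = (0.05, 0.5)
    frac_palindromic: float = 9 / 328
    inside_violated: bool = False  # correlate pleiotropy with gamma
    seed: int = 0

    def validate(self) -> None:
        if self.n_snps < 1:
            raise ValueError("n_snps must be >= 1")
        if self.gamma_sd < 0 or self.pleio_sd < 0:
            raise ValueError("sd values must be >= 0")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if not (0 <= self.frac_palindromic <= 1):
            raise ValueError("frac_palindromic must be in [0,1]")
        if self.case_fraction is not None and not (0 < self.case_fraction < 1):
            raise ValueError("case_fraction must be in (0,1)")


@dataclass
class SyntheticLookupConfig:
    """Generative parameters for a planted cross-trait look-up study."""

    n_loci: int = 40
    snps_per_locus: int = 3
    locus_spacing_bp: int = 2_000_000
    n_phenotypes: int = 15
    overlap_fraction: float = 1.0
    concordant_fraction: float = 1 / 3
    effect_p: float = 1e-6
    null_p_floor: float = 1e-3
    within_locus_span_bp: int = 100_000
    trait_label: str = "body mass index"
    seed: int = 0

    def validate(self) -> None:
        for f in ("overlap_fraction", "concordant_fraction"):
            if not (0 <= getattr(self, f) <= 1):
                raise ValueError(f"{f} must be in [0,1]")
        if self.locus_spacing_bp <= 2 * 500_000:
            raise ValueError("locus_spacing_bp must exceed 1 Mb so planted "
                             "loci are unambiguous")
        if self.n_loci < 1 or self.snps_per_locus < 1:
            raise ValueError("n_loci and snps_per_locus must be >= 1")
        if not (0 < self.effect_p < self.null_p_floor <= 1):
            raise ValueError("need 0 < effect_p < null_p_floor <= 1")


def _se_from_maf_n(maf: np.ndarray, n: int) -> np.ndarray:
    return 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * n)


def _assign_alleles(rng: np.random.Generator, n: int,
                    frac_palindromic: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    n_pal = int(round(frac_palindromic * n))
    pal_idx = np.zeros(n, dtype=bool)
    if n_pal:
        pal_idx[rng.choice(n, size=n_pal, replace=False)] = True
    ea = np.empty(n, dtype=object)
    oa = np.empty(n, dtype=object)
    for j in range(n):
        pool = _PALINDROMIC_PAIRS if pal_idx[j] else _NONPALINDROMIC_PAIRS
        a1, a2 = pool[rng.integers(len(pool))]
        ea[j], oa[j] = a1, a2
    return ea, oa, pal_idx


def _sumstat_frame(snp_ids, chrom, pos, ea, oa, eaf, beta, se, n, trait):
    p = 2 * stats.norm.sf(np.abs(np.asarray(beta) / np.asarray(se)))
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    return pd.DataFrame({
        "snp_id": snp_ids, "chrom": chrom, "pos": pos,
        "effect_allele": ea, "other_allele": oa, "eaf": eaf,
        "beta": beta, "se": se, "pvalue": p, "n": n, "trait": trait,
    }, columns=SUMSTAT_COLUMNS)


def simulate_mr_study(cfg: SyntheticMRConfig
                      ) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Generate exposure and outcome summary-statistic tables plus the
    latent truth record.

    Per SNP j: MAF ~ U(maf_range); gamma_j ~ N(gamma_mean, gamma_sd²);
    pleiotropy alpha_j ~ N(pleio_mean, pleio_sd²) (independent of
    gamma_j under InSIDE; proportional-plus-noise when
    ``inside_violated``); latent outcome effect ``true_beta * gamma_j +
    alpha_j``; observed betas add N(0, se²) noise with se from the
    MAF/sample-size approximation.  Identical configs and seeds give
    identical tables.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_snps
    maf = rng.uniform(*cfg.maf_range, size=n)
    gamma = rng.normal(cfg.gamma_mean, cfg.gamma_sd, size=n)
    if cfg.inside_violated and cfg.pleio_sd > 0:
        # direct effects proportional to instrument strength: InSIDE broken
        scale = gamma / max(abs(cfg.gamma_mean), 1e-12)
        alpha = cfg.pleio_mean * scale + rng.normal(
            0.0, cfg.pleio_sd, size=n) * scale
    else:
        alpha = rng.normal(cfg.pleio_mean, cfg.pleio_sd, size=n)
    latent_out = cfg.true_beta * gamma + alpha

    se_exp = _se_from_maf_n(maf, cfg.n_exposure)
    n_out_eff = cfg.n_outcome
    if cfg.case_fraction is not None:
        # binary outcome on the log-odds scale: var(beta) ~
        # 1/(2 MAF (1-MAF) N cf (1-cf)), i.e. effective N = N cf (1-cf)
        n_out_eff = int(cfg.n_outcome * cfg.case_fraction
                        * (1 - cfg.case_fraction))
    se_out = _se_from_maf_n(maf, n_out_eff)

    beta_exp = gamma + rng.normal(0.0, 1.0, size=n) * se_exp
    beta_out = latent_out + rng.normal(0.0, 1.0, size=n) * se_out

    ea, oa, pal_idx = _assign_alleles(rng, n, cfg.frac_palindromic)
    snp_ids = [f"rs{j + 1:06d}" for j in range(n)]
    chrom = [str(1 + j % 22) for j in range(n)]
    pos = [1_000_000 + 2_000_000 * (j // 22) for j in range(n)]

    exposure = _sumstat_frame(snp_ids, chrom, pos, ea, oa, maf,
                              beta_exp, se_exp, cfg.n_exposure, "exposure")
    outcome = _sumstat_frame(snp_ids, chrom, pos, ea, oa, maf,
                             beta_out, se_out, cfg.n_outcome, "outcome")
    truth = {
        "config": asdict(cfg),
        "true_beta": cfg.true_beta,
        "maf": maf.tolist(),
        "gamma": gamma.tolist(),
        "pleiotropy": alpha.tolist(),
        "latent_outcome": latent_out.tolist(),
        "palindromic": pal_idx.tolist(),
        "seed": cfg.seed,
    }
    return exposure, outcome, truth


def simulate_lookup_study(cfg: SyntheticLookupConfig
                          ) -> tuple[pd.DataFrame, dict[str, pd.DataFrame],
                                     pd.DataFrame, dict]:
    """Generate a planted look-up study.

    Returns ``(catalog, phenotype_tables, anthro_stats, truth)``.  Loci
    are separated by ``locus_spacing_bp`` (> 1 Mb) so positional
    clustering recovers them exactly.  For ``overlap_fraction`` of loci
    a designated member receives P = ``effect_p`` in one randomly
    chosen phenotype, with effect direction concordant with the
    anthropometric effect for ``concordant_fraction`` of those loci;
    every other (SNP, phenotype) pair is null with P >= null_p_floor.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n_snps = cfg.n_loci * cfg.snps_per_locus
    phenos = [f"phenotype_{k + 1:02d}" for k in range(cfg.n_phenotypes)]

    snp_ids, chroms, poss, locus_of = [], [], [], {}
    for i in range(cfg.n_loci):
        chrom = str(1 + i % 22)
        base = 1_000_000 + (i // 22) * (cfg.locus_spacing_bp + 1_000_000)
        offsets = np.sort(rng.integers(0, cfg.within_locus_span_bp,
                                       size=cfg.snps_per_locus))
        for j, off in enumerate(offsets):
            snp = f"rs{i + 1:03d}{j + 1:02d}"
            snp_ids.append(snp)
            chroms.append(chrom)
            poss.append(int(base + off))
            locus_of[snp] = i

    catalog = pd.DataFrame({
        "snp_id": snp_ids, "chrom": chroms, "pos": poss,
        "trait_label": cfg.trait_label,
        "pvalue": 10.0 ** rng.uniform(-20, np.log10(5e-8), size=n_snps),
        "study_id": "synthetic", "ancestry": "synthetic",
    }, columns=CATALOG_COLUMNS)

    # anthropometric stats: positive effect for the effect allele
    ea = ["A"] * n_snps
    oa = ["G"] * n_snps
    eaf = rng.uniform(0.1, 0.9, size=n_snps)
    anthro_beta = rng.uniform(0.02, 0.08, size=n_snps)
    anthro = _sumstat_frame(snp_ids, chroms, poss, ea, oa, eaf,
                            anthro_beta, np.full(n_snps, 0.003),
                            500_000, cfg.trait_label)

    n_overlap = int(round(cfg.overlap_fraction * cfg.n_loci))
    overlap_loci = sorted(rng.choice(cfg.n_loci, size=n_overlap,
                                     replace=False).tolist())
    n_conc = int(round(cfg.concordant_fraction * n_overlap))
    conc_flags = {loc: (k < n_conc)
                  for k, loc in enumerate(rng.permutation(overlap_loci).tolist())}
    designated = {loc: int(rng.integers(cfg.snps_per_locus))
                  for loc in overlap_loci}
    pheno_of_locus = {loc: phenos[int(rng.integers(cfg.n_phenotypes))]
                      for loc in overlap_loci}

    pheno_tables: dict[str, pd.DataFrame] = {}
    planted = []
    for pheno in phenos:
        beta = rng.normal(0.0, 0.005, size=n_snps)
        se = np.full(n_snps, 0.01)
        p = rng.uniform(cfg.null_p_floor, 1.0, size=n_snps)
        for loc in overlap_loci:
            if pheno_of_locus[loc] != pheno:
                continue
            j = loc * cfg.snps_per_locus + designated[loc]
            p[j] = cfg.effect_p
            mag = rng.uniform(0.05, 0.1)
            beta[j] = mag if conc_flags[loc] else -mag
            planted.append({
                "locus": loc, "snp_id": snp_ids[j], "phenotype": pheno,
                "concordant": bool(conc_flags[loc])})
        df = pd.DataFrame({
            "snp_id": snp_ids, "chrom": chroms, "pos": poss,
            "effect_allele": ea, "other_allele": oa, "eaf": eaf,
            "beta": beta, "se": se, "pvalue": p,
            "n": 100_000, "trait": pheno,
        }, columns=SUMSTAT_COLUMNS)
        pheno_tables[pheno] = df

    truth = {
        "config": asdict(cfg),
        "locus_of": locus_of,
        "overlap_loci": overlap_loci,
        "designated_lead": {loc: snp_ids[loc * cfg.snps_per_locus
                                         + designated[loc]]
                            for loc in overlap_loci},
        "phenotype_of_locus": pheno_of_locus,
        "planted_hits": planted,
        "seed": cfg.seed,
    }
    return catalog, pheno_tables, anthro, truth
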