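"""Synthetic inputs with known ground truth for every pipeline stage.

The generators emulate the structure of the study inputs without any real
data: a block-LD reference panel standing in for a European reference panel,
GWAS summary statistics whose Z-scores are exactly MVN(0, R) under the null
(odds ratios and standard errors are back-filled so log(OR)/SE reproduces Z
bit-exactly), negative-binomial count matrices with case/control log2 fold
changes and diagnosis-linked covariates, and per-tissue top-eQTL instrument
tables with a known causal effect.

Everything is a pure function of :class:`SimConfig` (seed-deterministic),
and the emitted tables round-trip through the package readers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .diffexpr import ExpressionStudy
from .genesets import GeneAnnotation, ReferencePanel
from .mr import MRInstrument

__all__ = [
    "SimConfig",
    "CountModel",
    "MRModel",
    "sim_reference_panel",
    "sim_gwas_sumstats",
    "sim_counts",
    "sim_mr",
    "sumstats_to_frame",
]

_NONPALINDROMIC_PAIRS = (
    ("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
    ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T"),
)


@dataclass(frozen=True)
class CountModel:
    """Count-matrix generator settings (postmortem-cohort-like defaults).

    The default design mirrors a 20-case / 19-control brain cohort; the tiny
    3 vs 3 design of the second expression dataset is obtained by overriding
    ``n_case``/``n_control``.  Mean counts are log-normal around ~25 (the
    scale of the focal gene in the source cohorts), NB dispersion 0.1, and
    DE genes change by log2 fold change 1.17 by default.  The logistic-model
    coefficients are the fitted values reported for the dichotomized
    analysis: age -0.01/yr, sex(male) 0.02, race(white) 2.71, PMI 0.11/hr,
    high expression 2.58.
    """

    n_case: int = 20
    n_control: int = 19
    n_genes: int = 200
    mean_log_mu: float = np.log(25.0)
    sd_log_mu: float = 1.0
    dispersion: float = 0.1
    lfc: float = 1.17
    de_fraction: float = 0.05
    coef_intercept: float = -2.5
    coef_age: float = -0.01
    coef_sex_male: float = 0.02
    coef_race_white: float = 2.71
    coef_pmi: float = 0.11
    coef_ge: float = 2.58


@dataclass(frozen=True)
class MRModel:
    """Instrument generator settings: 30 tissues, modest true causal effect."""

    n_tissues: int = 30
    theta: float = 0.1
    beta_exp_mean: float = 0.5
    beta_exp_sd: float = 0.1
    se_exp: float = 0.05
    se_out: float = 0.02
    n_palindromic: int = 3
    n_swapped: int = 5


@dataclass(frozen=True)
class SimConfig:
    """Study-scale defaults for the synthetic cohort.

    ``n_ref_samples`` defaults to 503 (the size of the phase-3 European
    reference panel the LD stands in for); SNP counts per gene, MAFs, and
    within-block exchangeable LD are at typical gene-panel scales; summary
    statistics get INFO in [0.85, 1] so the 0.9 QC filter is exercised, plus
    deliberately injected strand-ambiguous and duplicate-rsid rows.
    """

    seed: int = 2025
    n_ref_samples: int = 503
    n_genes: int = 200
    snps_per_gene: tuple[int, int] = (4, 12)
    ld_block_rho: float = 0.5
    maf_range: tuple[float, float] = (0.05, 0.5)
    causal_gene_fraction: float = 0.01
    signal_mean_shift: float = 0.8
    info_range: tuple[float, float] = (0.85, 1.0)
    se_range: tuple[float, float] = (0.02, 0.05)
    allele_swap_fraction: float = 0.2
    n_ambiguous: int = 5
    n_dup_pairs: int = 3
    count_model: CountModel = field(default_factory=CountModel)
    mr_model: MRModel = field(default_factory=MRModel)

    def rng(self, salt: int = 0) -> np.random.Generator:
        return np.random.default_rng((int(self.seed), int(salt)))


def sim_reference_panel(cfg: SimConfig) -> tuple[ReferencePanel, list[GeneAnnotation]]:
    """Block-LD dosage panel plus consistent gene annotation.

    Each gene is one exchangeable-correlation block: every haplotype allele
    copies a gene-shared draw with probability sqrt(rho), making the
    pairwise dosage correlation rho in expectation.  The gene's MAF is drawn
    uniformly from ``maf_range``.
    """
    rng = cfg.rng(salt=1)
    lo, hi = cfg.snps_per_gene
    gamma = np.sqrt(cfg.ld_block_rho)
    genes: list[GeneAnnotation] = []
    rows = []
    blocks = []
    rs_counter = 100000
    per_chrom_index: dict[int, int] = {}
    for g in range(cfg.n_genes):
        chrom = g % 22 + 1
        k = per_chrom_index.get(chrom, 0)
        per_chrom_index[chrom] = k + 1
        m = int(rng.integers(lo, hi + 1))
        tx_start = 1_000_000 * (k + 1)
        positions = tx_start + 150 * np.arange(m)
        tx_end = int(positions[-1])
        maf = float(rng.uniform(*cfg.maf_range))

        # shared-draw construction: exact pairwise haplotype correlation rho
        n = cfg.n_ref_samples
        u_common = rng.random(size=(n, 2, 1))
        u_indep = rng.random(size=(n, 2, m))
        copies = rng.random(size=(n, 2, m)) < gamma
        u = np.where(copies, u_common, u_indep)
        dosage = (u < maf).sum(axis=1).astype(float)
        blocks.append(dosage)

        gene = GeneAnnotation(
            gene_id=f"GENE{g:05d}",
            symbol=f"G{g}",
            chrom=str(chrom),
            tx_start=int(tx_start),
            tx_end=tx_end,
        )
        genes.append(gene)
        for j, pos in enumerate(positions):
            ref, alt = _NONPALINDROMIC_PAIRS[int(rng.integers(len(_NONPALINDROMIC_PAIRS)))]
            rows.append(
                {
                    "chrom": str(chrom),
                    "pos": int(pos),
                    "rsid": f"rs{rs_counter}",
                    "ref": ref,
                    "alt": alt,
                }
            )
            rs_counter += 1
    panel = ReferencePanel(variants=pd.DataFrame(rows), dosages=np.hstack(blocks))
    return panel, genes


def sim_gwas_sumstats(
    panel: ReferencePanel,
    genes: list[GeneAnnotation],
    cfg: SimConfig,
    salt: int = 2,
    causal_genes=None,
) -> tuple[pd.DataFrame, dict]:
    """Summary statistics with known per-gene truth.

    Null genes draw ``z ~ MVN(0, R_sample)`` on the panel's sample LD;
    causal genes add ``signal_mean_shift`` to every SNP's mean.  OR and SE
    are back-filled from z so ``log(OR)/SE`` recovers it exactly.  A
    configured number of strand-ambiguous rows and duplicate-rsid pairs is
    injected (with clean INFO) to exercise QC bookkeeping.  ``causal_genes``
    overrides the random causal-gene choice (e.g. to redraw a replication
    cohort with the discovery cohort's signal genes).
    """
    rng = cfg.rng(salt=salt)
    if causal_genes is not None:
        causal_ids = set(causal_genes)
    else:
        n_causal = int(round(cfg.causal_gene_fraction * len(genes)))
        causal_ids = set(
            rng.choice([g.gene_id for g in genes], size=n_causal, replace=False).tolist()
        ) if n_causal else set()

    variants = panel.variants
    by_gene: dict[str, list[int]] = {}
    for g in genes:
        lo, hi = g.tx_start, g.tx_end
        idx = variants.index[
            (variants["chrom"] == g.chrom)
            & (variants["pos"] >= lo)
            & (variants["pos"] <= hi)
        ].tolist()
        by_gene[g.gene_id] = idx

    rows = []
    truth_rows = []
    for g in genes:
        idx = by_gene[g.gene_id]
        X = panel.dosages[:, idx]
        R = np.corrcoef(X, rowvar=False)
        R = np.atleast_2d(R)
        L = np.linalg.cholesky(R + 1e-9 * np.eye(R.shape[0]))
        z = L @ rng.standard_normal(R.shape[0])
        if g.gene_id in causal_ids:
            z = z + cfg.signal_mean_shift
        se = rng.uniform(*cfg.se_range, size=z.size)
        info = rng.uniform(*cfg.info_range, size=z.size)
        swap = rng.random(z.size) < cfg.allele_swap_fraction
        for j, vi in enumerate(idx):
            var = variants.iloc[vi]
            zj = float(z[j])
            a1, a2 = var["alt"], var["ref"]
            z_rep = zj
            if swap[j]:  # report the other allele as effect allele
                a1, a2 = a2, a1
                z_rep = -zj
            rows.append(
                {
                    "CHR": var["chrom"],
                    "SNP": var["rsid"],
                    "BP": int(var["pos"]),
                    "A1": a1,
                    "A2": a2,
                    "INFO": round(float(info[j]), 4),
                    "OR": np.exp(z_rep * se[j]),
                    "SE": se[j],
                    "P": float(2.0 * norm.sf(abs(zj))),
                }
            )
            truth_rows.append(
                {"gene_id": g.gene_id, "rsid": var["rsid"], "z_true": zj,
                 "info": float(info[j])}
            )

    max_pos = int(variants["pos"].max()) + 10_000_000
    for k in range(cfg.n_ambiguous):
        rows.append(
            {
                "CHR": "22", "SNP": f"rsambig{k}", "BP": max_pos + k,
                "A1": "A", "A2": "T", "INFO": 0.99,
                "OR": float(np.exp(rng.normal(0, 0.02))),
                "SE": 0.03, "P": 0.5,
            }
        )
    for k in range(cfg.n_dup_pairs):
        for copy in range(2):
            rows.append(
                {
                    "CHR": "21", "SNP": f"rsdup{k}", "BP": max_pos + 1000 + 2 * k + copy,
                    "A1": "A", "A2": "G", "INFO": 0.99,
                    "OR": float(np.exp(rng.normal(0, 0.02))),
                    "SE": 0.03, "P": 0.5,
                }
            )

    truth = {
        "causal_genes": sorted(causal_ids),
        "signal_mean_shift": cfg.signal_mean_shift,
        "n_injected_ambiguous": cfg.n_ambiguous,
        "n_injected_duplicate_rows": 2 * cfg.n_dup_pairs,
        "n_low_info": int(sum(t["info"] < 0.9 for t in truth_rows)),
        "snp_truth": pd.DataFrame(truth_rows),
    }
    return pd.DataFrame(rows), truth


def sumstats_to_frame(df: pd.DataFrame, path) -> None:
    """Write a generated summary-statistics table in daner layout."""
    df.to_csv(path, sep="\t", index=False)


def sim_counts(
    cfg: SimConfig, link_covariates: bool = False, salt: int = 3
) -> tuple[ExpressionStudy, pd.DataFrame]:
    """NB count matrix with covariates and known DE truth.

    Without covariate linkage the first ``n_case`` samples are cases and DE
    genes multiply the case mean by ``2**lfc``.  With ``link_covariates``
    the diagnosis is drawn from the dichotomized-expression logistic model:
    the focal gene (first row) gets counts whose median split reproduces a
    designed balanced high/low indicator, and the diagnosis probability
    follows the model coefficients; remaining genes are null.
    """
    cm = cfg.count_model
    rng = cfg.rng(salt=salt)
    n = cm.n_case + cm.n_control
    sample_ids = [f"S{i:03d}" for i in range(n)]

    age = np.clip(rng.normal(45.0, 15.0, size=n), 18.0, 90.0)
    pmi = np.clip(rng.normal(15.0, 5.0, size=n), 2.0, 40.0)
    sex = np.where(rng.random(n) < 0.75, "male", "female")
    race = np.where(rng.random(n) < 0.7, "white", "non-white")

    base_mu = np.exp(rng.normal(cm.mean_log_mu, cm.sd_log_mu, size=cm.n_genes))
    n_de = int(round(cm.de_fraction * cm.n_genes))
    is_de = np.zeros(cm.n_genes, dtype=bool)

    if link_covariates:
        ge = np.zeros(n, dtype=int)
        ge[rng.permutation(n)[: n // 2]] = 1
        eta = (
            cm.coef_intercept
            + cm.coef_age * age
            + cm.coef_sex_male * (sex == "male")
            + cm.coef_race_white * (race == "white")
            + cm.coef_pmi * pmi
            + cm.coef_ge * ge
        )
        diagnosis = np.where(rng.random(n) < 1.0 / (1.0 + np.exp(-eta)), "case", "control")
        counts = np.empty((cm.n_genes, n))
        # focal gene: disjoint low/high ranges so the median split recovers ge
        counts[0] = np.where(ge == 1, rng.integers(25, 41, size=n), rng.integers(5, 16, size=n))
        disp = cm.dispersion
        for i in range(1, cm.n_genes):
            counts[i] = rng.negative_binomial(1.0 / disp, 1.0 / (1.0 + disp * base_mu[i]), size=n)
        case = diagnosis == "case"
    else:
        diagnosis = np.array(["case"] * cm.n_case + ["control"] * cm.n_control)
        case = diagnosis == "case"
        ge = None
        if n_de:
            is_de[rng.permutation(cm.n_genes)[:n_de]] = True
        disp = cm.dispersion
        counts = np.empty((cm.n_genes, n))
        for i in range(cm.n_genes):
            mu = np.full(n, base_mu[i])
            if is_de[i]:
                mu[case] *= 2.0**cm.lfc
            counts[i] = rng.negative_binomial(1.0 / disp, 1.0 / (1.0 + disp * mu))

    gene_ids = [f"GENE{i:05d}" for i in range(cm.n_genes)]
    study = ExpressionStudy(
        counts=pd.DataFrame(counts.astype(int), index=gene_ids, columns=sample_ids),
        samples=pd.DataFrame(
            {
                "diagnosis": diagnosis,
                "age_at_death": age,
                "sex": sex,
                "race": race,
                "pmi": pmi,
            },
            index=pd.Index(sample_ids, name="sample_id"),
        ),
    )
    truth = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "true_lfc": np.where(is_de, cm.lfc, 0.0),
            "is_de": is_de,
        }
    )
    if link_covariates:
        truth.attrs["ge_indicator"] = ge
        truth.attrs["coefficients"] = {
            "const": cm.coef_intercept,
            "age_at_death": cm.coef_age,
            "sex_male": cm.coef_sex_male,
            "race_white": cm.coef_race_white,
            "pmi": cm.coef_pmi,
            "high_expression": cm.coef_ge,
        }
    return study, truth


def sim_mr(cfg: SimConfig, salt: int = 4) -> tuple[list[MRInstrument], dict]:
    """Per-tissue instrument pairs with a known causal effect theta.

    Outcome betas are ``theta * (true exposure effect) + noise``.  A
    configured number of tissues gets swapped outcome allele order (with a
    consistently negated beta, recoverable by harmonization) and a further
    set gets palindromic alleles with eaf near 0.5 (must be dropped).
    """
    mm = cfg.mr_model
    rng = cfg.rng(salt=salt)
    instruments: list[MRInstrument] = []
    swapped = set(rng.choice(mm.n_tissues, size=min(mm.n_swapped, mm.n_tissues), replace=False).tolist())
    for t in range(mm.n_tissues):
        beta_true = rng.normal(mm.beta_exp_mean, mm.beta_exp_sd)
        beta_exp = beta_true + rng.normal(0.0, mm.se_exp)
        beta_out = mm.theta * beta_true + rng.normal(0.0, mm.se_out)
        ea, oa = _NONPALINDROMIC_PAIRS[int(rng.integers(len(_NONPALINDROMIC_PAIRS)))]
        eaf = float(rng.uniform(0.1, 0.9))
        if t in swapped:
            out_alleles = (oa, ea)
            out_beta = -beta_out
            out_eaf = 1.0 - eaf
        else:
            out_alleles = (ea, oa)
            out_beta = beta_out
            out_eaf = eaf
        instruments.append(
            MRInstrument(
                tissue=f"tissue_{t:02d}",
                rsid=f"rsmr{t:03d}",
                exposure_beta=float(beta_exp),
                exposure_se=mm.se_exp,
                outcome_beta=float(out_beta),
                outcome_se=mm.se_out,
                exposure_alleles=(ea, oa),
                outcome_alleles=out_alleles,
                exposure_eaf=eaf,
                outcome_eaf=out_eaf,
            )
        )
    palindromic = []
    for k in range(mm.n_palindromic):
        palindromic.append(
            MRInstrument(
                tissue=f"tissue_pal_{k:02d}",
                rsid=f"rspal{k:03d}",
                exposure_beta=float(rng.normal(mm.beta_exp_mean, mm.beta_exp_sd)),
                exposure_se=mm.se_exp,
                outcome_beta=float(rng.normal(0.0, mm.se_out)),
                outcome_se=mm.se_out,
                exposure_alleles=("A", "T"),
                outcome_alleles=("A", "T"),
                exposure_eaf=0.45,
                outcome_eaf=0.45,
            )
        )
    truth = {
        "theta": mm.theta,
        "n_tissues": mm.n_tissues,
        "swapped_tissues": sorted(f"tissue_{t:02d}" for t in swapped),
        "palindromic_tissues": [p.tissue for p in palindromic],
    }
    return instruments + palindromic, truth


def instruments_to_tables(instruments: list[MRInstrument]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Serialize instruments as exposure/outcome TSV-shaped tables."""
    exp_rows, out_rows = [], []
    for i in instruments:
        exp_rows.append(
            {
                "tissue": i.tissue, "rsid": i.rsid, "beta": i.exposure_beta,
                "se": i.exposure_se, "effect_allele": i.exposure_alleles[0],
                "other_allele": i.exposure_alleles[1], "eaf": i.exposure_eaf,
            }
        )
        out_rows.append(
            {
                "tissue": i.tissue, "rsid": i.rsid, "beta": i.outcome_beta,
                "se": i.outcome_se, "effect_allele": i.outcome_alleles[0],
                "other_allele": i.outcome_alleles[1], "eaf": i.outcome_eaf,
            }
        )
    return pd.DataFrame(exp_rows), pd.DataFrame(out_rows)
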