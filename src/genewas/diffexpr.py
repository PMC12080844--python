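"""Two differential-expression analyses on bulk RNA-seq count matrices.

1. Dichotomized-expression logistic regression (case/control postmortem
   cohorts, e.g. 20 cases / 19 controls): each gene's counts are split at the
   sample median into low (<= median) / high (> median); the diagnosis is
   regressed on age at death, sex, race (white vs. non-white reference), PMI
   (postmortem interval, hours), and the high-expression indicator; the
   gene's p-value is the Wald Z test on that indicator.  A white-only variant
   drops the race term.

2. A minimal negative-binomial count model (tiny designs such as 3 cases /
   3 controls): genes with total count >= 10 are normalized by
   median-of-ratios size factors and tested by a Wald test on the diagnosis
   coefficient of an NB log-link GLM with method-of-moments dispersion;
   p-values are Benjamini-Hochberg adjusted.  This is deliberately a minimal
   re-implementation of the standard NB-GLM workflow, not a feature-complete
   clone of any published tool.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import norm, t as t_dist
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import PerfectSeparationError

__all__ = [
    "ExpressionStudy",
    "LogisticDEResult",
    "TermStats",
    "DegeneratePredictorError",
    "SeparationError",
    "dichotomize",
    "wald_stats",
    "fit_logistic_de",
    "logistic_de_table",
    "size_factors",
    "nb_de",
    "bh_adjust",
    "fold_change",
]

#: absolute cap on reported log2 fold changes when one class has zero counts
LFC_CLAMP = 10.0

_META_COLUMNS = ("diagnosis", "age_at_death", "sex", "race", "pmi")


class DegeneratePredictorError(ValueError):
    """A predictor (e.g. dichotomized expression) is constant."""


class SeparationError(ValueError):
    """(Quasi-)complete separation makes a logistic term non-estimable."""


@dataclass
class ExpressionStudy:
    """A gene x sample count matrix with per-sample covariates.

    ``counts``: DataFrame indexed by gene id, one column per sample id.
    ``samples``: DataFrame indexed by sample id with columns diagnosis
    ({case, control}), age_at_death (years), sex ({male, female}), race
    (categorical; "white" vs. anything else), pmi (hours).
    """

    counts: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.counts.columns) != list(self.samples.index):
            raise ValueError("count columns must match sample metadata index")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        missing = [c for c in _META_COLUMNS if c not in self.samples.columns]
        if missing:
            raise ValueError(f"sample metadata missing columns: {missing}")

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def subset(self, sample_ids) -> "ExpressionStudy":
        sample_ids = list(sample_ids)
        return ExpressionStudy(
            counts=self.counts[sample_ids], samples=self.samples.loc[sample_ids]
        )


@dataclass(frozen=True)
class TermStats:
    beta: float
    se: float
    z: float
    p: float


@dataclass(frozen=True)
class LogisticDEResult:
    gene_id: str
    terms: dict[str, TermStats]
    n: int

    @property
    def p_expression(self) -> float:
        return self.terms["high_expression"].p


def wald_stats(beta: float, se: float) -> TermStats:
    """Wald Z test for a fitted coefficient: z = beta/se, p = 2*Phi(-|z|)."""
    if se <= 0:
        raise ValueError(f"standard error must be positive, got {se}")
    z = beta / se
    return TermStats(beta=float(beta), se=float(se), z=float(z), p=float(2.0 * norm.sf(abs(z))))


def dichotomize(counts_row) -> np.ndarray:
    """Split a gene's counts at the median: 0 = low (<= median), 1 = high.

    The median is taken over exactly the samples in the analysis set, so a
    subset analysis (e.g. white-only) recomputes it.
    """
    x = np.asarray(counts_row, dtype=float).ravel()
    if x.size < 2:
        raise ValueError("dichotomization needs at least 2 samples")
    return (x > np.median(x)).astype(int)


def fit_logistic_de(
    study: ExpressionStudy, gene_id: str, include_race: bool = True
) -> LogisticDEResult:
    """Fit diagnosis ~ age + sex (+ race) + pmi + high-expression for one gene.

    Raises :class:`DegeneratePredictorError` when the dichotomized expression
    (or any covariate) is constant and :class:`SeparationError` on
    (quasi-)complete separation.
    """
    meta = study.samples
    y = (meta["diagnosis"].astype(str).str.lower() == "case").to_numpy(float)
    if y.min() == y.max():
        raise ValueError("diagnosis must contain both cases and controls")
    ge = dichotomize(study.counts.loc[gene_id].to_numpy())
    design = {
        "age_at_death": meta["age_at_death"].to_numpy(float),
        "sex_male": (meta["sex"].astype(str).str.lower() == "male").to_numpy(float),
        "pmi": meta["pmi"].to_numpy(float),
        "high_expression": ge.astype(float),
    }
    if include_race:
        design["race_white"] = (
            meta["race"].astype(str).str.lower() == "white"
        ).to_numpy(float)
    X = pd.DataFrame(design, index=meta.index)
    for name, col in X.items():
        if np.ptp(col.to_numpy()) == 0.0:
            raise DegeneratePredictorError(f"{gene_id}: predictor {name!r} is constant")
        if name == "high_expression" and (
            np.array_equal(col.to_numpy(), y) or np.array_equal(1.0 - col.to_numpy(), y)
        ):
            raise SeparationError(
                f"{gene_id}: term 'high_expression' perfectly separates diagnosis"
            )
    Xc = sm.add_constant(X, prepend=True)
    try:
        # convergence is verified explicitly below; silence the interim noise
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.Logit(y, Xc).fit(method="newton", maxiter=200, tol=1e-10, disp=0)
    except (PerfectSeparationError, np.linalg.LinAlgError) as exc:
        raise SeparationError(f"{gene_id}: logistic fit is non-estimable ({exc})")
    params, bse = fit.params, fit.bse
    if not fit.mle_retvals.get("converged", True) or np.any(np.abs(params) > 30):
        term = params.drop("const").abs().idxmax()
        raise SeparationError(f"{gene_id}: term {term!r} appears non-estimable")
    terms = {
        name: wald_stats(float(params[name]), float(bse[name])) for name in Xc.columns
    }
    return LogisticDEResult(gene_id=gene_id, terms=terms, n=len(y))


def logistic_de_table(
    study: ExpressionStudy,
    gene_ids=None,
    include_race: bool = True,
    white_only: bool = False,
) -> pd.DataFrame:
    """Per-gene, per-term logistic DE table (beta, se, z, p).

    ``white_only=True`` restricts the analysis set to white participants and
    drops the race term (the self-consistent subset analysis: medians are
    recomputed on the subset).  Genes whose fit is degenerate or separated
    are reported with a ``status`` column instead of estimates.
    """
    if white_only:
        white = study.samples.index[
            study.samples["race"].astype(str).str.lower() == "white"
        ]
        study = study.subset(white)
        include_race = False
    gene_ids = list(gene_ids) if gene_ids is not None else list(study.counts.index)
    rows = []
    for g in gene_ids:
        try:
            res = fit_logistic_de(study, g, include_race=include_race)
        except (DegeneratePredictorError, SeparationError) as exc:
            rows.append({"gene_id": g, "term": None, "status": str(exc)})
            continue
        for term, st in res.terms.items():
            rows.append(
                {
                    "gene_id": g,
                    "term": term,
                    "beta": st.beta,
                    "se": st.se,
                    "z": st.z,
                    "p": st.p,
                    "status": "ok",
                }
            )
    return pd.DataFrame(rows)


def size_factors(counts, pseudo_reference: bool = False) -> np.ndarray:
    """Median-of-ratios per-sample scale factors, normalized to geometric mean 1.

    The reference profile is the per-gene geometric mean over genes with
    all-positive counts; ``pseudo_reference=True`` falls back to geometric
    means over the positive entries only (usable when no gene is expressed
    in every sample).
    """
    X = np.asarray(counts, dtype=float)
    if X.ndim != 2:
        raise ValueError("counts must be a genes x samples matrix")
    if X.shape[1] == 1:
        return np.array([1.0])
    with np.errstate(divide="ignore"):
        logX = np.where(X > 0, np.log(X), np.nan)
    if pseudo_reference:
        ref = np.nanmean(logX, axis=1)
        usable = ~np.isnan(ref)
    else:
        ref = logX.mean(axis=1)
        usable = np.isfinite(ref)
    if not usable.any():
        raise ValueError(
            "no gene has positive counts in every sample; "
            "retry with pseudo_reference=True"
        )
    log_ratios = logX[usable] - ref[usable, None]
    log_sf = np.nanmedian(log_ratios, axis=0)
    log_sf = log_sf - np.nanmean(log_sf)  # geometric mean 1
    return np.exp(log_sf)


def _mom_dispersion(y_norm: np.ndarray, groups: np.ndarray, floor: float = 1e-8) -> float:
    """Method-of-moments NB dispersion from normalized counts.

    Solves the moment equation E[(y - mu)^2] = mu + alpha mu^2 within
    diagnosis groups, with a small-sample variance correction.
    """
    num = 0.0
    den = 0.0
    for g in np.unique(groups):
        yg = y_norm[groups == g]
        if yg.size < 2:
            continue
        mu = yg.mean()
        resid2 = np.sum((yg - mu) ** 2) * yg.size / (yg.size - 1)
        num += resid2 - yg.size * mu
        den += yg.size * mu * mu
    if den <= 0:
        return floor
    return max(num / den, floor)


def nb_de(study: ExpressionStudy, min_total: int = 10, sf: np.ndarray | None = None) -> pd.DataFrame:
    """Negative-binomial differential expression, case vs. control.

    Genes with total count < ``min_total`` are excluded.  Per retained gene:
    NB log-link GLM of counts on diagnosis with log size factor offset,
    method-of-moments dispersion (floored at 1e-8), Wald test on the
    diagnosis coefficient; log2 fold changes; BH adjustment over the retained
    genes.  When one class has all-zero counts the fit uses a half-count
    pseudo-observation, the LFC is clamped to +-10, and ``lfc_clamped`` is
    flagged.
    """
    meta = study.samples
    case = (meta["diagnosis"].astype(str).str.lower() == "case").to_numpy(float)
    if case.min() == case.max():
        raise ValueError("diagnosis must contain both cases and controls")
    counts = study.counts
    totals = counts.sum(axis=1)
    kept = counts.loc[totals >= min_total]
    if sf is None:
        sf = size_factors(kept.to_numpy())
    offset = np.log(sf)
    X = sm.add_constant(pd.DataFrame({"diagnosis_case": case}, index=meta.index))
    rows = []
    for g, y in kept.iterrows():
        y = y.to_numpy(float)
        clamped = False
        y_fit = y
        if y[case == 1].sum() == 0 or y[case == 0].sum() == 0:
            y_fit = y + 0.5
            clamped = True
        alpha = _mom_dispersion(y_fit / sf, case)
        model = sm.GLM(
            y_fit, X, family=sm.families.NegativeBinomial(alpha=alpha), offset=offset
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = model.fit(maxiter=200, tol=1e-10)
        beta = float(fit.params["diagnosis_case"])
        se = float(fit.bse["diagnosis_case"])
        zval = beta / se
        lfc = beta / np.log(2.0)
        if clamped:
            lfc = float(np.clip(lfc, -LFC_CLAMP, LFC_CLAMP))
        # t reference with residual df: the plug-in dispersion makes the
        # normal-referenced Wald test anti-conservative at small n
        rows.append(
            {
                "gene_id": g,
                "base_mean": float((y / sf).mean()),
                "lfc": lfc,
                "p": float(2.0 * t_dist.sf(abs(zval), max(len(y) - 2, 1))),
                "lfc_clamped": clamped,
            }
        )
    out = pd.DataFrame(rows, columns=["gene_id", "base_mean", "lfc", "p", "lfc_clamped"])
    if len(out):
        out["p_adj"] = bh_adjust(out["p"].to_numpy())
    else:
        out["p_adj"] = pd.Series(dtype=float)
    return out


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, input order preserved."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must be in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def fold_change(lfc: float) -> float:
    """Multiplicative expression factor corresponding to a log2 fold change."""
    return float(2.0**lfc)
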