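"""Single-instrument two-sample Mendelian randomization by Wald ratio.

Per tissue, the top eQTL for the exposure gene is paired with the same SNP's
effect in the outcome GWAS (log-odds scale).  Effect directions are
harmonized so both sides refer to the same effect allele; palindromic (A/T,
C/G) instruments are retained only when allele frequencies on both sides
make the orientation inferable and concordant, otherwise dropped.  The
causal effect per tissue is the Wald ratio ``beta_out / beta_exp`` with the
first-order delta-method standard error ``se_out / |beta_exp|``; tissues are
flagged against a Bonferroni threshold ``alpha / n_tested``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.stats import norm

from .assoc import bonferroni_threshold

__all__ = [
    "MRInstrument",
    "MRResult",
    "WeakInstrumentError",
    "harmonize_pair",
    "wald_ratio",
    "mr_scan",
    "read_instrument_tables",
]

#: palindromic instruments with min(eaf, 1-eaf) above this cannot be oriented
PALINDROME_MAF_LIMIT = 0.42

_AMBIGUOUS = ({"A", "T"}, {"C", "G"})


class WeakInstrumentError(ValueError):
    """The exposure effect is zero; the Wald ratio is non-estimable."""


@dataclass(frozen=True)
class MRInstrument:
    """A harmonizable exposure/outcome effect pair for one tissue's top eQTL."""

    tissue: str
    rsid: str
    exposure_beta: float
    exposure_se: float
    outcome_beta: float
    outcome_se: float
    exposure_alleles: tuple[str, str]  # (effect, other)
    outcome_alleles: tuple[str, str]
    exposure_eaf: float | None = None
    outcome_eaf: float | None = None

    def __post_init__(self) -> None:
        if self.exposure_se <= 0 or self.outcome_se <= 0:
            raise ValueError(f"{self.tissue}/{self.rsid}: standard errors must be positive")


@dataclass(frozen=True)
class MRResult:
    tissue: str
    rsid: str
    beta: float
    se: float
    p: float


def _is_palindromic(alleles: tuple[str, str]) -> bool:
    return set(alleles) in _AMBIGUOUS


def harmonize_pair(
    inst: MRInstrument, palindrome_maf_limit: float = PALINDROME_MAF_LIMIT
) -> tuple[MRInstrument | None, str]:
    """Align the outcome effect to the exposure's effect allele.

    Returns ``(harmonized, reason)``; the instrument is None when dropped.
    Swapped outcome allele order flips the outcome beta (and eaf).
    Palindromic variants need known allele frequencies on both sides, both
    inferable (maf < limit), and concordant orientation; anything else drops.
    """
    exp = tuple(a.upper() for a in inst.exposure_alleles)
    out = tuple(a.upper() for a in inst.outcome_alleles)
    if out == exp:
        flipped = False
    elif out == (exp[1], exp[0]):
        flipped = True
    else:
        return None, "alleles_irreconcilable"
    aligned = inst
    if flipped:
        aligned = replace(
            inst,
            outcome_beta=-inst.outcome_beta,
            outcome_alleles=exp,
            outcome_eaf=None if inst.outcome_eaf is None else 1.0 - inst.outcome_eaf,
        )
    if _is_palindromic(exp):
        e_eaf, o_eaf = aligned.exposure_eaf, aligned.outcome_eaf
        if e_eaf is None or o_eaf is None:
            return None, "palindromic_missing_eaf"
        if min(e_eaf, 1 - e_eaf) >= palindrome_maf_limit or min(
            o_eaf, 1 - o_eaf
        ) >= palindrome_maf_limit:
            return None, "palindromic_not_inferable"
        if (e_eaf - 0.5) * (o_eaf - 0.5) <= 0:
            return None, "palindromic_discordant"
    return aligned, "flipped" if flipped else "ok"


def wald_ratio(inst: MRInstrument, second_order: bool = False) -> MRResult:
    """Wald-ratio causal estimate for one harmonized instrument.

    The default SE is the first-order delta method, ignoring exposure-side
    noise; ``second_order=True`` adds the exposure-variance term
    ``beta_out^2 * se_exp^2 / beta_exp^4``.
    """
    if inst.exposure_beta == 0:
        raise WeakInstrumentError(f"{inst.tissue}/{inst.rsid}: exposure effect is zero")
    beta = inst.outcome_beta / inst.exposure_beta
    se = inst.outcome_se / abs(inst.exposure_beta)
    if second_order:
        se = np.sqrt(
            se**2 + inst.outcome_beta**2 * inst.exposure_se**2 / inst.exposure_beta**4
        )
    z = beta / se
    return MRResult(
        tissue=inst.tissue,
        rsid=inst.rsid,
        beta=float(beta),
        se=float(se),
        p=float(2.0 * norm.sf(abs(z))),
    )


def mr_scan(
    instruments: list[MRInstrument],
    alpha: float = 0.05,
    palindrome_maf_limit: float = PALINDROME_MAF_LIMIT,
) -> tuple[pd.DataFrame, float | None, pd.DataFrame]:
    """Harmonize and test every tissue's instrument.

    Returns (results, threshold, harmonization_log).  The Bonferroni
    threshold is ``alpha`` over the tissues actually tested (dropped
    instruments do not count).
    """
    log_rows, results = [], []
    for inst in instruments:
        harm, reason = harmonize_pair(inst, palindrome_maf_limit=palindrome_maf_limit)
        log_rows.append({"tissue": inst.tissue, "rsid": inst.rsid, "status": reason})
        if harm is None:
            continue
        res = wald_ratio(harm)
        results.append(
            {"tissue": res.tissue, "rsid": res.rsid, "beta": res.beta, "se": res.se, "p": res.p}
        )
    out = pd.DataFrame(results, columns=["tissue", "rsid", "beta", "se", "p"])
    if len(out):
        threshold = bonferroni_threshold(len(out), alpha)
        out["significant"] = out["p"] <= threshold
    else:
        threshold = None
        out["significant"] = pd.Series(dtype=bool)
    return out, threshold, pd.DataFrame(log_rows, columns=["tissue", "rsid", "status"])


def read_instrument_tables(exposure_path, outcome_path) -> list[MRInstrument]:
    """Build instruments from exposure and outcome TSVs.

    Both files carry: tissue, rsid, beta, se, effect_allele, other_allele,
    eaf (the outcome table may repeat one GWAS record across tissues).
    Tissues present on only one side are skipped.
    """
    exp = pd.read_csv(exposure_path, sep="\t")
    out = pd.read_csv(outcome_path, sep="\t")
    merged = exp.merge(out, on=["tissue", "rsid"], suffixes=("_exp", "_out"))
    instruments = []
    for row in merged.itertuples(index=False):
        instruments.append(
            MRInstrument(
                tissue=row.tissue,
                rsid=row.rsid,
                exposure_beta=float(row.beta_exp),
                exposure_se=float(row.se_exp),
                outcome_beta=float(row.beta_out),
                outcome_se=float(row.se_out),
                exposure_alleles=(str(row.effect_allele_exp), str(row.other_allele_exp)),
                outcome_alleles=(str(row.effect_allele_out), str(row.other_allele_out)),
                exposure_eaf=None if pd.isna(row.eaf_exp) else float(row.eaf_exp),
                outcome_eaf=None if pd.isna(row.eaf_out) else float(row.eaf_out),
            )
        )
    return instruments
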