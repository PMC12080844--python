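"""Both differential-expression analyses on the synthetic cohorts.

The 20/19 cohort gets the dichotomized-expression logistic model (all
samples, and the white-only variant without the race term); the 3/3 cohort
gets the negative-binomial count model with BH adjustment.  Tables land
under results/de/.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
import config  # noqa: E402

from genewas.diffexpr import ExpressionStudy, fold_change  # noqa: E402
from genewas.pipeline import run_de  # noqa: E402


def load_study(counts_path, samples_path) -> ExpressionStudy:
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    samples = pd.read_csv(samples_path, sep="\t", index_col=0)
    return ExpressionStudy(counts=counts, samples=samples)


def main() -> None:
    config.require_inputs()
    logistic_study = load_study(config.FILES["counts_logistic"], config.FILES["samples_logistic"])
    count_study = load_study(config.FILES["counts_small"], config.FILES["samples_small"])
    tables = run_de(logistic_study, count_study, out_dir=config.RESULTS_DIR / "de")

    ge = tables["logistic_all_samples"]
    ge = ge[(ge.term == "high_expression") & (ge.status == "ok")]
    print(f"logistic DE (all samples): {ge.shape[0]} genes fitted; "
          f"{(ge.p <= 0.05).sum()} with expression p <= 0.05")
    top = ge.nsmallest(3, "p")
    for row in top.itertuples():
        print(f"  {row.gene_id}  beta={row.beta:.2f}  se={row.se:.2f}  z={row.z:.2f}  p={row.p:.3f}")

    nb = tables["nb_counts"]
    print(f"NB count DE (3v3): {len(nb)} genes tested; "
          f"{(nb.p_adj <= 0.05).sum()} at BH-adjusted p <= 0.05, "
          f"{(nb.p <= 0.05).sum()} at raw p <= 0.05 "
          "(three samples per arm leave little power)")
    for row in nb.nsmallest(5, "p").itertuples():
        print(f"  {row.gene_id}  LFC={row.lfc:.2f} (factor {fold_change(row.lfc):.2f})  "
              f"p={row.p:.2e}  p_adj={row.p_adj:.2e}")
    print(f"tables written under {config.RESULTS_DIR / 'de'}")


if __name__ == "__main__":
    main()
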