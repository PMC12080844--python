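"""Shared configuration for the numbered analysis scripts.

One synthetic cohort drives the whole narrative: a discovery GWAS with a few
strong signal genes, an independent replication GWAS sharing those genes at
a weaker effect, two expression cohorts (a 20/19 postmortem design for the
dichotomized logistic analysis and a 3/3 design for the count model), and a
30-tissue top-eQTL instrument set with a known causal effect.
"""

from pathlib import Path

from genewas.simulate import CountModel, MRModel, SimConfig

ROOT = Path(__file__).resolve().parents[1]
DATA_DIR = ROOT / "scratch" / "analysis_data"
RESULTS_DIR = ROOT / "results"

SEED = 2025

#: discovery GWAS: 200 genes, 3 signal genes at a strong per-SNP z shift
DISCOVERY = SimConfig(
    seed=SEED,
    n_genes=200,
    causal_gene_fraction=3 / 200,
    signal_mean_shift=4.0,
)

#: replication draws new Z-scores for the same genes at a weaker shift
#: (smaller replication cohorts see the same signal with less power)
REPLICATION_SHIFT = 2.0
REPLICATION_SALT = 12

#: expression cohorts
LOGISTIC_COHORT = SimConfig(
    seed=SEED + 1, count_model=CountModel(n_case=20, n_control=19, n_genes=50)
)
COUNT_COHORT = SimConfig(
    seed=SEED + 2,
    count_model=CountModel(n_case=3, n_control=3, n_genes=400, de_fraction=0.02),
)

#: 30-tissue instrument set with true causal effect 0.1
MR_STUDY = SimConfig(seed=SEED + 3, mr_model=MRModel(theta=0.1, n_tissues=30))

FILES = {
    "sumstats_discovery": DATA_DIR / "sumstats_discovery.tsv",
    "sumstats_replication": DATA_DIR / "sumstats_replication.tsv",
    "panel": DATA_DIR / "panel.tsv",
    "genes": DATA_DIR / "genes.tsv",
    "counts_logistic": DATA_DIR / "counts_logistic.tsv",
    "samples_logistic": DATA_DIR / "samples_logistic.tsv",
    "counts_small": DATA_DIR / "counts_small.tsv",
    "samples_small": DATA_DIR / "samples_small.tsv",
    "mr_exposure": DATA_DIR / "mr_exposure.tsv",
    "mr_outcome": DATA_DIR / "mr_outcome.tsv",
    "truth": DATA_DIR / "truth.json",
}


def require_inputs() -> None:
    missing = [str(p) for p in FILES.values() if not p.exists()]
    if missing:
        raise SystemExit(
            "synthetic inputs missing - run analysis/01_simulate_inputs.py first:\n  "
            + "\n  ".join(missing)
        )
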