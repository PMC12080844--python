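"""Replication of discovery hits in the independent synthetic GWAS.

Takes the genes flagged in the discovery scan, computes their adaptive-test
p-values in the replication summary statistics, and reports replicated /
near-boundary / untestable status at alpha = 0.05.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
import config  # noqa: E402

from genewas.pipeline import run_replication  # noqa: E402


def main() -> None:
    config.require_inputs()
    disc_path = config.RESULTS_DIR / "discovery" / "gene_results.tsv"
    if not disc_path.exists():
        raise SystemExit("run analysis/02_discovery_scan.py first")
    disc = pd.read_csv(disc_path, sep="\t")
    hits = disc.loc[disc.significant, "gene_id"].tolist()
    if not hits:
        raise SystemExit("no discovery hits to replicate")
    table = run_replication(
        hits,
        config.FILES["sumstats_replication"],
        config.FILES["panel"],
        config.FILES["genes"],
        alpha=0.05,
        out_dir=config.RESULTS_DIR / "replication",
    )
    print("replication at alpha = 0.05:")
    for row in table.itertuples():
        p = "NA" if row.p_at is None else f"{row.p_at:.4g}"
        flag = " (near boundary)" if row.near_boundary else ""
        print(f"  {row.gene_id}  p={p}  {row.status}{flag}")
    print(f"tables written under {config.RESULTS_DIR / 'replication'}")


if __name__ == "__main__":
    main()
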