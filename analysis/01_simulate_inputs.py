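"""Generate every synthetic input the downstream analyses consume.

Writes the discovery and replication GWAS summary statistics, the LD
reference panel and gene annotation, the two expression cohorts, and the
per-tissue MR instrument tables (plus a truth file) under
scratch/analysis_data/.  All of it is a deterministic function of the seeds
in analysis/config.py.
"""

import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
import config  # noqa: E402

from genewas.genesets import write_panel_tsv  # noqa: E402
from genewas.simulate import (  # noqa: E402
    instruments_to_tables,
    sim_counts,
    sim_gwas_sumstats,
    sim_mr,
    sim_reference_panel,
)


def main() -> None:
    config.DATA_DIR.mkdir(parents=True, exist_ok=True)
    f = config.FILES

    panel, genes = sim_reference_panel(config.DISCOVERY)
    write_panel_tsv(panel, f["panel"])
    with open(f["genes"], "w") as fh:
        fh.write("gene_id\tsymbol\tchrom\ttx_start\ttx_end\tstrand\n")
        for g in genes:
            fh.write(f"{g.gene_id}\t{g.symbol}\t{g.chrom}\t{g.tx_start}\t{g.tx_end}\t{g.strand}\n")

    disc, truth = sim_gwas_sumstats(panel, genes, config.DISCOVERY)
    disc.to_csv(f["sumstats_discovery"], sep="\t", index=False)

    from dataclasses import replace

    rep_cfg = replace(config.DISCOVERY, signal_mean_shift=config.REPLICATION_SHIFT)
    rep, _ = sim_gwas_sumstats(
        panel, genes, rep_cfg, salt=config.REPLICATION_SALT,
        causal_genes=truth["causal_genes"],
    )
    rep.to_csv(f["sumstats_replication"], sep="\t", index=False)

    log_study, log_truth = sim_counts(config.LOGISTIC_COHORT)
    log_study.counts.to_csv(f["counts_logistic"], sep="\t")
    log_study.samples.to_csv(f["samples_logistic"], sep="\t")

    cnt_study, cnt_truth = sim_counts(config.COUNT_COHORT)
    cnt_study.counts.to_csv(f["counts_small"], sep="\t")
    cnt_study.samples.to_csv(f["samples_small"], sep="\t")

    instruments, mr_truth = sim_mr(config.MR_STUDY)
    exp, out = instruments_to_tables(instruments)
    exp.to_csv(f["mr_exposure"], sep="\t", index=False)
    out.to_csv(f["mr_outcome"], sep="\t", index=False)

    truth_out = {
        "causal_genes": truth["causal_genes"],
        "n_injected_ambiguous": truth["n_injected_ambiguous"],
        "n_injected_duplicate_rows": truth["n_injected_duplicate_rows"],
        "de_genes_count_cohort": cnt_truth.loc[cnt_truth.is_de, "gene_id"].tolist(),
        "mr_theta": mr_truth["theta"],
        "mr_palindromic_tissues": mr_truth["palindromic_tissues"],
    }
    f["truth"].write_text(json.dumps(truth_out, indent=2) + "\n")

    print(f"reference panel: {panel.dosages.shape[0]} samples x {panel.dosages.shape[1]} variants, {len(genes)} genes")
    print(f"discovery sumstats: {len(disc)} rows; signal genes: {', '.join(truth['causal_genes'])}")
    print(f"replication sumstats: {len(rep)} rows at per-SNP shift {config.REPLICATION_SHIFT}")
    print(f"logistic cohort: {log_study.counts.shape[0]} genes x {log_study.n_samples} samples")
    print(f"count cohort: {cnt_study.counts.shape[0]} genes x {cnt_study.n_samples} samples "
          f"({len(truth_out['de_genes_count_cohort'])} DE genes at LFC {config.COUNT_COHORT.count_model.lfc})")
    print(f"MR instruments: {len(instruments)} tissues (true theta = {mr_truth['theta']})")
    print(f"written under {config.DATA_DIR}")


if __name__ == "__main__":
    main()
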