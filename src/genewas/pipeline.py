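"""Orchestrated runs: discovery scan, replication, DE follow-up, MR.

Each ``run_*`` function executes one configured stage end to end on
in-memory objects or file paths, optionally writes its tables under an
output directory, and returns the results together with a
:class:`RunManifest` (configuration snapshot, per-stage record counts,
thresholds, output digests, seed) so identical inputs reproduce identical
result files.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .assoc import DEFAULT_RHO_GRID, adaptive_test, genome_scan
from .diffexpr import ExpressionStudy, logistic_de_table, nb_de
from .genesets import GeneAnnotation, ReferencePanel, build_gene_sets, read_gene_annotation, read_panel_tsv
from .mr import MRInstrument, mr_scan, read_instrument_tables
from .sumstats import compute_z_all, qc_filter, read_sumstats

__all__ = [
    "RunManifest",
    "DiscoveryResult",
    "run_discovery",
    "run_replication",
    "run_de",
    "run_mr",
]

logger = logging.getLogger("genewas")

#: replication p-values above alpha but below this multiple are flagged as
#: near the boundary (e.g. p = 0.059 at alpha = 0.05)
NEAR_BOUNDARY_FACTOR = 1.25


@dataclass
class RunManifest:
    stage: str
    seed: int | None
    config: dict
    counts: dict
    thresholds: dict
    outputs: dict = field(default_factory=dict)
    version: str = __version__

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, default=str) + "\n")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_outputs(manifest: RunManifest, out_dir: str | Path, tables: dict[str, pd.DataFrame]) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for name, df in tables.items():
        p = out_dir / f"{name}.tsv"
        df.to_csv(p, sep="\t", index=False)
        manifest.outputs[str(p)] = _sha256(p)
    mpath = out_dir / f"{manifest.stage}_manifest.json"
    manifest.write(mpath)


def _load_records(sumstats, dialect=None):
    if isinstance(sumstats, (str, Path)):
        return read_sumstats(sumstats, dialect=dialect)
    return list(sumstats), 0


def _load_panel(panel) -> ReferencePanel:
    if isinstance(panel, (str, Path)):
        return read_panel_tsv(panel)
    return panel


def _load_genes(genes) -> list[GeneAnnotation]:
    if isinstance(genes, (str, Path)):
        return read_gene_annotation(genes)
    return list(genes)


@dataclass
class DiscoveryResult:
    results: pd.DataFrame
    threshold: float | None
    manhattan: pd.DataFrame
    qc_counts: dict
    n_dropped_rows: int
    drop_log: pd.DataFrame
    manifest: RunManifest


def run_discovery(
    sumstats,
    panel,
    genes,
    *,
    flank: int = 1000,
    info_min: float = 0.9,
    alpha: float = 0.05,
    rho_grid=DEFAULT_RHO_GRID,
    dialect: dict | None = None,
    seed: int | None = None,
    out_dir: str | Path | None = None,
) -> DiscoveryResult:
    """QC -> gene assignment -> LD -> prune -> genome scan.

    ``sumstats`` / ``panel`` / ``genes`` may be file paths or in-memory
    objects.  Genes with adaptive p at or below the Bonferroni threshold over
    the genes tested are flagged significant.
    """
    records, n_dropped = _load_records(sumstats, dialect=dialect)
    panel = _load_panel(panel)
    genes = _load_genes(genes)
    kept, qc_counts = qc_filter(records, info_min=info_min)
    kept = compute_z_all(kept)
    sets, drop_log = build_gene_sets(kept, panel, genes, flank=flank)
    if not sets:
        logger.warning("discovery: no gene set survived QC and assembly")
    results, threshold, manhattan = genome_scan(sets, alpha=alpha, rho_grid=rho_grid)
    manifest = RunManifest(
        stage="discovery",
        seed=seed,
        config={
            "flank": flank,
            "info_min": info_min,
            "alpha": alpha,
            "rho_grid": list(rho_grid),
        },
        counts={
            "input_rows": len(records) + n_dropped,
            "unparseable_rows": n_dropped,
            "qc_removed": qc_counts,
            "qc_retained": len(kept),
            "genes_annotated": len(genes),
            "genes_tested": len(results),
            "significant_genes": int(results["significant"].sum()) if len(results) else 0,
        },
        thresholds={"bonferroni": threshold},
    )
    out = DiscoveryResult(
        results=results,
        threshold=threshold,
        manhattan=manhattan,
        qc_counts=qc_counts,
        n_dropped_rows=n_dropped,
        drop_log=drop_log,
        manifest=manifest,
    )
    if out_dir is not None:
        _write_outputs(manifest, out_dir, {
            "gene_results": results, "manhattan": manhattan, "assembly_drops": drop_log,
        })
    return out


def run_replication(
    discovery_hits,
    sumstats,
    panel,
    genes,
    *,
    alpha: float = 0.05,
    flank: int = 1000,
    info_min: float = 0.9,
    rho_grid=DEFAULT_RHO_GRID,
    dialect: dict | None = None,
    out_dir: str | Path | None = None,
) -> pd.DataFrame:
    """Adaptive-test p-values in replication data for named discovery hits.

    A hit absent from the replication data is reported as untestable rather
    than erroring; p-values just above alpha are flagged near-boundary and
    reported verbatim.
    """
    hits = list(discovery_hits)
    if not hits:
        raise ValueError("discovery hit list is empty")
    records, _ = _load_records(sumstats, dialect=dialect)
    panel = _load_panel(panel)
    genes = [g for g in _load_genes(genes) if g.gene_id in set(hits)]
    kept, _ = qc_filter(records, info_min=info_min)
    kept = compute_z_all(kept)
    sets, _ = build_gene_sets(kept, panel, genes, flank=flank)
    by_id = {s.gene.gene_id: s for s in sets}
    rows = []
    for h in hits:
        gs = by_id.get(h)
        if gs is None:
            rows.append({"gene_id": h, "p_at": None, "status": "untestable",
                         "near_boundary": False})
            continue
        at = adaptive_test(gs.z, gs.R, rho_grid=rho_grid)
        replicated = at.p < alpha
        rows.append(
            {
                "gene_id": h,
                "p_at": at.p,
                "status": "replicated" if replicated else "not_replicated",
                "near_boundary": (not replicated) and at.p <= NEAR_BOUNDARY_FACTOR * alpha,
            }
        )
    table = pd.DataFrame(rows, columns=["gene_id", "p_at", "status", "near_boundary"])
    if out_dir is not None:
        manifest = RunManifest(
            stage="replication", seed=None,
            config={"alpha": alpha, "hits": hits},
            counts={"hits": len(hits),
                    "testable": int(table["status"].ne("untestable").sum())},
            thresholds={"alpha": alpha},
        )
        _write_outputs(manifest, out_dir, {"replication": table})
    return table


def run_de(
    logistic_study: ExpressionStudy,
    count_study: ExpressionStudy,
    *,
    gene_ids=None,
    min_total: int = 10,
    out_dir: str | Path | None = None,
) -> dict[str, pd.DataFrame]:
    """Both differential-expression analyses.

    Returns the all-samples and white-only dichotomized logistic tables for
    ``logistic_study`` and the NB count-model table for ``count_study``.
    """
    all_samples = logistic_de_table(logistic_study, gene_ids=gene_ids, include_race=True)
    white_only = logistic_de_table(logistic_study, gene_ids=gene_ids, white_only=True)
    counts_table = nb_de(count_study, min_total=min_total)
    tables = {
        "logistic_all_samples": all_samples,
        "logistic_white_only": white_only,
        "nb_counts": counts_table,
    }
    if out_dir is not None:
        manifest = RunManifest(
            stage="de", seed=None,
            config={"min_total": min_total},
            counts={
                "logistic_samples": logistic_study.n_samples,
                "count_samples": count_study.n_samples,
                "nb_genes_tested": len(counts_table),
            },
            thresholds={},
        )
        _write_outputs(manifest, out_dir, tables)
    return tables


def run_mr(
    instruments,
    outcome=None,
    *,
    alpha: float = 0.05,
    out_dir: str | Path | None = None,
):
    """Harmonize -> Wald ratio per tissue -> Bonferroni flagging.

    ``instruments`` is either a list of :class:`MRInstrument` or an exposure
    table path (with ``outcome`` the matching outcome table path).  Subset
    runs (e.g. European-only panels) are just separate calls on the subset.
    """
    if not isinstance(instruments, list):
        instruments = read_instrument_tables(instruments, outcome)
    results, threshold, log = mr_scan(instruments, alpha=alpha)
    if out_dir is not None:
        manifest = RunManifest(
            stage="mr", seed=None,
            config={"alpha": alpha},
            counts={"instruments": len(instruments), "tested": len(results),
                    "significant": int(results["significant"].sum()) if len(results) else 0},
            thresholds={"bonferroni": threshold},
        )
        _write_outputs(manifest, out_dir, {"mr_results": results, "harmonization_log": log})
    return results, threshold, log
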