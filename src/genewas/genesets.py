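"""Gene windows, reference-panel harmonization, LD matrices, and pruning.

QC-passed variants are grouped into per-gene SNP sets: a gene's window is its
transcription span plus a flank (default +-1000 bp, both ends inclusive),
alleles are harmonized against a reference genotype panel (Z signs flipped
when the effect/other order is reversed), the gene-wide LD matrix is the
Pearson correlation of panel dosages, and one member of each perfectly
correlated pair (r = 1) is pruned.  Genes retaining fewer than two variants
are dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .sumstats import VariantSummary

__all__ = [
    "GeneAnnotation",
    "ReferencePanel",
    "GeneSnpSet",
    "ZeroVarianceError",
    "assign_to_gene",
    "harmonize_to_panel",
    "ld_matrix",
    "prune_perfect_ld",
    "build_gene_sets",
    "read_gene_annotation",
    "read_panel_tsv",
    "read_panel_vcf",
]

class ZeroVarianceError(ValueError):
    """A variant selected for LD estimation has constant dosage."""


@dataclass(frozen=True)
class GeneAnnotation:
    """A gene's transcription span on an autosome (1-based, inclusive)."""

    gene_id: str
    symbol: str
    chrom: str
    tx_start: int
    tx_end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.tx_start > self.tx_end:
            raise ValueError(f"{self.gene_id}: tx_start > tx_end")

    @property
    def midpoint(self) -> int:
        return (self.tx_start + self.tx_end) // 2


@dataclass
class ReferencePanel:
    """Reference genotypes: a variant table plus a sample x variant dosage matrix.

    ``variants`` must carry columns ``chrom, pos, rsid, ref, alt``; dosages
    are additive counts of the alt allele in [0, 2].
    """

    variants: pd.DataFrame
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.variants = self.variants.reset_index(drop=True)
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2 or self.dosages.shape[1] != len(self.variants):
            raise ValueError("dosage matrix must be n_samples x n_variants")
        if self.dosages.shape[0] < 2:
            raise ValueError("reference panel needs at least 2 samples")
        self._by_rsid = {r: i for i, r in enumerate(self.variants["rsid"])}
        self._by_locus = {
            (str(c), int(p)): i
            for i, (c, p) in enumerate(zip(self.variants["chrom"], self.variants["pos"]))
        }

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    def lookup(self, rsid: str, chrom: str | None = None, pos: int | None = None):
        """Find a variant row by rsid (primary) or chrom:pos (fallback).

        Returns ``(index, row)`` or ``None``.  An rsid hit whose position
        disagrees with the query position is treated as a miss (the caller
        drops the variant with a reason).
        """
        i = self._by_rsid.get(rsid)
        if i is not None:
            row = self.variants.iloc[i]
            if pos is not None and int(row["pos"]) != int(pos):
                return None
            return i, row
        if chrom is not None and pos is not None:
            i = self._by_locus.get((str(chrom), int(pos)))
            if i is not None:
                return i, self.variants.iloc[i]
        return None


@dataclass
class GeneSnpSet:
    """A gene's harmonized Z-vector with its LD correlation matrix."""

    gene: GeneAnnotation
    rsids: list[str]
    z: np.ndarray
    R: np.ndarray
    positions: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        self.R = np.asarray(self.R, dtype=float)
        m = len(self.rsids)
        if self.z.shape != (m,) or self.R.shape != (m, m):
            raise ValueError(f"{self.gene.gene_id}: inconsistent set dimensions")

    @property
    def m(self) -> int:
        return len(self.rsids)


def assign_to_gene(
    variants: list[VariantSummary], gene: GeneAnnotation, flank: int = 1000
) -> list[VariantSummary]:
    """Variants inside the gene window [tx_start - flank, tx_end + flank]."""
    lo, hi = gene.tx_start - flank, gene.tx_end + flank
    return [v for v in variants if v.chrom == gene.chrom and lo <= v.pos <= hi]


def harmonize_to_panel(variant: VariantSummary, panel_variant) -> float | None:
    """Align a variant's Z to the panel's alt allele.

    Returns the (possibly sign-flipped) Z, or None when the allele pairs are
    irreconcilable.  ``panel_variant`` is a mapping with ``ref``/``alt``.
    """
    if variant.z is None:
        raise ValueError(f"{variant.rsid}: Z must be computed before harmonization")
    ea, oa = variant.effect_allele, variant.other_allele
    ref, alt = str(panel_variant["ref"]), str(panel_variant["alt"])
    if (ea, oa) == (alt, ref):
        return float(variant.z)
    if (ea, oa) == (ref, alt):
        return -float(variant.z)
    return None


def ld_matrix(panel: ReferencePanel, rsids: list[str]) -> np.ndarray:
    """Pearson correlation of panel dosages for an ordered rsid list."""
    idx = []
    for r in rsids:
        hit = panel.lookup(r)
        if hit is None:
            raise KeyError(f"variant {r} not in reference panel")
        idx.append(hit[0])
    X = panel.dosages[:, idx]
    sd = X.std(axis=0)
    for j, s in enumerate(sd):
        if s == 0.0:
            raise ZeroVarianceError(f"variant {rsids[j]} has zero dosage variance")
    R = np.corrcoef(X, rowvar=False)
    R = np.atleast_2d(R)
    np.fill_diagonal(R, 1.0)
    return R


def prune_perfect_ld(gene_set: GeneSnpSet, epsilon: float = 1e-8) -> GeneSnpSet | None:
    """Remove one member of every perfectly correlated (r >= 1 - epsilon) pair.

    Deterministic order: while any offending pair exists, the later-position
    member of the lexicographically smallest offending index pair is removed.
    Returns None when fewer than two variants survive.  Only r = +1 pairs are
    pruned; r = -1 pairs are retained.
    """
    keep = list(range(gene_set.m))
    R = gene_set.R
    while len(keep) >= 2:
        offender = None
        for a in range(len(keep)):
            for b in range(a + 1, len(keep)):
                if R[keep[a], keep[b]] >= 1.0 - epsilon:
                    offender = b
                    break
            if offender is not None:
                break
        if offender is None:
            break
        del keep[offender]
    if len(keep) < 2:
        return None
    idx = np.asarray(keep)
    return GeneSnpSet(
        gene=gene_set.gene,
        rsids=[gene_set.rsids[i] for i in keep],
        z=gene_set.z[idx],
        R=gene_set.R[np.ix_(idx, idx)],
        positions=[gene_set.positions[i] for i in keep] if gene_set.positions else [],
    )


def build_gene_sets(
    variants: list[VariantSummary],
    panel: ReferencePanel,
    genes: list[GeneAnnotation],
    flank: int = 1000,
    epsilon: float = 1e-8,
    min_snps: int = 2,
) -> tuple[list[GeneSnpSet], pd.DataFrame]:
    """Assemble per-gene SNP sets from QC-passed, Z-scored variants.

    Returns the retained sets and a drop log (gene_id, rsid, reason) covering
    harmonization failures, panel misses, zero-variance variants, pruning,
    and genes falling below ``min_snps``.
    """
    drops: list[tuple[str, str, str]] = []
    sets: list[GeneSnpSet] = []
    for gene in genes:
        cand = assign_to_gene(variants, gene, flank=flank)
        cand.sort(key=lambda v: (v.pos, v.rsid))
        rsids, zs, positions = [], [], []
        for v in cand:
            hit = panel.lookup(v.rsid, chrom=v.chrom, pos=v.pos)
            if hit is None:
                drops.append((gene.gene_id, v.rsid, "not_in_panel_or_position_mismatch"))
                continue
            z = harmonize_to_panel(v, hit[1])
            if z is None:
                drops.append((gene.gene_id, v.rsid, "alleles_irreconcilable"))
                continue
            rsids.append(v.rsid)
            zs.append(z)
            positions.append(v.pos)
        # zero-variance variants cannot enter the correlation estimate
        usable = []
        for r, z, p in zip(rsids, zs, positions):
            col = panel.dosages[:, panel.lookup(r)[0]]
            if col.std() == 0.0:
                drops.append((gene.gene_id, r, "zero_dosage_variance"))
            else:
                usable.append((r, z, p))
        if len(usable) < min_snps:
            drops.append((gene.gene_id, "*", "fewer_than_min_snps"))
            continue
        rsids = [u[0] for u in usable]
        gs = GeneSnpSet(
            gene=gene,
            rsids=rsids,
            z=np.array([u[1] for u in usable]),
            R=ld_matrix(panel, rsids),
            positions=[u[2] for u in usable],
        )
        pruned = prune_perfect_ld(gs, epsilon=epsilon)
        if pruned is None:
            drops.append((gene.gene_id, "*", "fewer_than_min_snps_after_pruning"))
            continue
        for r in set(gs.rsids) - set(pruned.rsids):
            drops.append((gene.gene_id, r, "perfect_ld_pruned"))
        sets.append(pruned)
    log = pd.DataFrame(drops, columns=["gene_id", "rsid", "reason"])
    return sets, log


def read_gene_annotation(path: str | Path) -> list[GeneAnnotation]:
    """Read a headered BED-like TSV: gene_id, symbol, chrom, tx_start, tx_end, strand.

    Coordinates are 1-based inclusive (hg19-style annotation exported that
    way); a 0-based half-open BED can be converted by adding 1 to starts.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    return [
        GeneAnnotation(
            gene_id=row["gene_id"],
            symbol=row.get("symbol", row["gene_id"]),
            chrom=str(row["chrom"]),
            tx_start=int(row["tx_start"]),
            tx_end=int(row["tx_end"]),
            strand=row.get("strand", "+"),
        )
        for _, row in df.iterrows()
    ]


def read_panel_tsv(path: str | Path) -> ReferencePanel:
    """Read a headered dosage TSV: chrom, pos, rsid, ref, alt, then one column per sample."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    meta = df[["chrom", "pos", "rsid", "ref", "alt"]]
    dosages = df.drop(columns=["chrom", "pos", "rsid", "ref", "alt"]).to_numpy(float).T
    return ReferencePanel(variants=meta, dosages=dosages)


def write_panel_tsv(panel: ReferencePanel, path: str | Path) -> None:
    dosage_cols = pd.DataFrame(
        panel.dosages.T,
        columns=[f"S{i:04d}" for i in range(panel.n_samples)],
        index=panel.variants.index,
    )
    pd.concat([panel.variants, dosage_cols], axis=1).to_csv(path, sep="\t", index=False)


def write_gene_sets(sets: list[GeneSnpSet], out_dir: str | Path) -> None:
    """Serialize gene sets as paired TSVs: ``<gene>.variants.tsv`` (rsid,
    pos, z) and ``<gene>.ld.tsv`` (the correlation matrix, rsid-labelled)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for gs in sets:
        pd.DataFrame(
            {
                "rsid": gs.rsids,
                "pos": gs.positions if gs.positions else [0] * gs.m,
                "z": gs.z,
            }
        ).to_csv(out_dir / f"{gs.gene.gene_id}.variants.tsv", sep="\t", index=False)
        pd.DataFrame(gs.R, index=gs.rsids, columns=gs.rsids).to_csv(
            out_dir / f"{gs.gene.gene_id}.ld.tsv", sep="\t"
        )


def read_gene_set(gene: GeneAnnotation, in_dir: str | Path) -> GeneSnpSet:
    """Load one serialized gene set written by :func:`write_gene_sets`."""
    in_dir = Path(in_dir)
    var = pd.read_csv(in_dir / f"{gene.gene_id}.variants.tsv", sep="\t")
    ld = pd.read_csv(in_dir / f"{gene.gene_id}.ld.tsv", sep="\t", index_col=0)
    if list(ld.index) != list(var["rsid"]):
        raise ValueError(f"{gene.gene_id}: LD matrix labels disagree with variant table")
    return GeneSnpSet(
        gene=gene,
        rsids=var["rsid"].tolist(),
        z=var["z"].to_numpy(float),
        R=ld.to_numpy(float),
        positions=var["pos"].astype(int).tolist(),
    )


def read_panel_vcf(path: str | Path) -> ReferencePanel:
    """Read a VCF reference panel (GT, or DS when present) via cyvcf2."""
    from cyvcf2 import VCF  # optional dependency, imported lazily

    vcf = VCF(str(path))
    rows, cols = [], []
    for var in vcf:
        if len(var.ALT) != 1:
            continue
        if "DS" in (var.FORMAT or []):
            ds = np.asarray(var.format("DS"), dtype=float).ravel()
        else:
            gts = np.asarray(var.genotype.array())[:, :2]
            ds = np.where(gts < 0, np.nan, gts).sum(axis=1).astype(float)
        rows.append(
            {
                "chrom": str(var.CHROM).removeprefix("chr"),
                "pos": int(var.POS),
                "rsid": var.ID or f"{var.CHROM}:{var.POS}",
                "ref": var.REF,
                "alt": var.ALT[0],
            }
        )
        cols.append(ds)
    dosages = np.vstack(cols).T
    return ReferencePanel(variants=pd.DataFrame(rows), dosages=dosages)
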