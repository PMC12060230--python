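"""Gene-window association and candidate-gene flagging.

A gene is linked to a genomic window if a qualifying exon overlaps the
window, or if one of its qualifying exons is the first exon to the left or
to the right of the window boundaries (capturing potential regulatory
regions).  Two qualification modes mirror the two annotation passes of the
analysis: ``any_exon`` (coding or noncoding) for general QTL-interval
annotation, and ``coding_exon`` for differentiation-outlier windows.

Coordinates: GFF3 input (1-based closed) is normalized to 0-based half-open
internally; BED passes through.  Strand is carried but ignored by the
overlap/nearest rules.  Ties in nearest-exon distance link all tied genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Exon:
    start: int  # 0-based half-open
    end: int
    coding: bool

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"empty exon interval [{self.start}, {self.end})")


@dataclass
class GeneModel:
    gene_id: str
    symbol: str
    arm: str
    strand: str
    exons: tuple[Exon, ...]

    def qualifying_exons(self, mode: str) -> tuple[Exon, ...]:
        if mode == "any_exon":
            return self.exons
        if mode == "coding_exon":
            return tuple(e for e in self.exons if e.coding)
        raise ValueError(f"unknown mode {mode!r}")


def read_gff3(path) -> list[GeneModel]:
    """Gene models (exon lists with coding flags) from a GFF3 file.

    Exons are collected per gene through the Parent chain; an exon is flagged
    coding when it overlaps any CDS record of the same gene.
    """
    import gffutils

    db = gffutils.create_db(str(path), dbfn=":memory:", force=True,
                            merge_strategy="create_unique", keep_order=True)
    genes = []
    for g in db.features_of_type("gene"):
        exons, cds = [], []
        for e in db.children(g, featuretype="exon"):
            exons.append((e.start - 1, e.end))  # GFF3 1-based closed -> half-open
        for c in db.children(g, featuretype="CDS"):
            cds.append((c.start - 1, c.end))
        models = tuple(
            Exon(s, e, any(cs < e and ce > s for cs, ce in cds))
            for s, e in sorted(set(exons))
        )
        symbol = g.attributes.get("Name", [g.id])[0]
        genes.append(GeneModel(g.id, symbol, g.seqid, g.strand, models))
    return genes


def read_exon_bed(path) -> list[GeneModel]:
    """Gene models from a simple exon BED: chrom start end gene_id coding strand.

    The 5th column (BED score slot) carries the coding flag (1/0); missing
    trailing columns default to coding, strand '.'.
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df = df.rename(columns=dict(enumerate(["arm", "start", "end", "gene_id", "coding", "strand"])))
    if "coding" not in df:
        df["coding"] = 1
    if "strand" not in df:
        df["strand"] = "."
    genes = []
    for gid, sub in df.groupby("gene_id", sort=False):
        exons = tuple(Exon(int(r.start), int(r.end), bool(int(r.coding)))
                      for r in sub.itertuples())
        genes.append(GeneModel(str(gid), str(gid), str(sub["arm"].iloc[0]),
                               str(sub["strand"].iloc[0]), tuple(sorted(exons, key=lambda e: e.start))))
    return genes


def write_gff3(genes: list[GeneModel], path) -> None:
    """Minimal GFF3 writer (gene -> mRNA -> exon/CDS), inverse of read_gff3."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            lo = min(e.start for e in g.exons) + 1
            hi = max(e.end for e in g.exons)
            fh.write(f"{g.arm}\tsongqtl\tgene\t{lo}\t{hi}\t.\t{g.strand}\t.\t"
                     f"ID={g.gene_id};Name={g.symbol}\n")
            mid = f"{g.gene_id}.t1"
            fh.write(f"{g.arm}\tsongqtl\tmRNA\t{lo}\t{hi}\t.\t{g.strand}\t.\t"
                     f"ID={mid};Parent={g.gene_id}\n")
            for k, e in enumerate(g.exons):
                fh.write(f"{g.arm}\tsongqtl\texon\t{e.start + 1}\t{e.end}\t.\t{g.strand}\t.\t"
                         f"ID={g.gene_id}.e{k};Parent={mid}\n")
                if e.coding:
                    fh.write(f"{g.arm}\tsongqtl\tCDS\t{e.start + 1}\t{e.end}\t.\t{g.strand}\t0\t"
                             f"ID={g.gene_id}.c{k};Parent={mid}\n")


def load_gene_list(path) -> set[str]:
    """One gene id per line; blank lines and '#' comments ignored."""
    with open(path) as fh:
        return {line.strip() for line in fh
                if line.strip() and not line.startswith("#")}


def window_gene_links(
    windows: pd.DataFrame, genes: list[GeneModel], mode: str = "any_exon"
) -> pd.DataFrame:
    """Link genes to windows by exon overlap or nearest flanking exon.

    ``windows`` needs ``arm``, ``start``, ``end`` columns (0-based
    half-open).  Returns one row per (window, gene, link type) with the bp
    distance (0 for overlaps).  Link types: ``overlap``, ``nearest_left``,
    ``nearest_right``; an overlapping gene can additionally be a nearest
    flanking gene through a different exon.
    """
    by_arm: dict[str, list[tuple[int, int, str]]] = {}
    for g in genes:
        for e in g.qualifying_exons(mode):
            by_arm.setdefault(g.arm, []).append((e.start, e.end, g.gene_id))
    rows = []
    for widx, w in windows.iterrows():
        arm, ws, we = str(w["arm"]), int(w["start"]), int(w["end"])
        exons = by_arm.get(arm)
        if not exons:
            logger.warning("window %s:[%d,%d) has no genes on its arm", arm, ws, we)
            continue
        seen = set()
        for es, ee, gid in exons:
            if es < we and ee > ws and (gid, "overlap") not in seen:
                rows.append((widx, arm, ws, we, gid, "overlap", 0))
                seen.add((gid, "overlap"))
        left = [(ws - ee, gid) for es, ee, gid in exons if ee <= ws]
        if left:
            dmin = min(d for d, _ in left)
            for gid in {g for d, g in left if d == dmin}:
                rows.append((widx, arm, ws, we, gid, "nearest_left", dmin))
        right = [(es - we, gid) for es, ee, gid in exons if es >= we]
        if right:
            dmin = min(d for d, _ in right)
            for gid in {g for d, g in right if d == dmin}:
                rows.append((widx, arm, ws, we, gid, "nearest_right", dmin))
    out = pd.DataFrame(rows, columns=["window", "arm", "start", "end",
                                      "gene_id", "link", "distance"])
    return out.sort_values(["window", "gene_id", "link"]).reset_index(drop=True)


def flag_candidates(
    links: pd.DataFrame,
    lists: dict[str, set[str]],
    known_genes: set[str] | None = None,
    outlier_windows: set | None = None,
) -> pd.DataFrame:
    """Per-gene boolean flags from curated candidate lists.

    ``lists`` maps a list name (e.g. ``male_mating_behavior``) to gene ids;
    ids absent from ``known_genes`` (when given) are warned about and
    ignored.  Genes linked to any window in ``outlier_windows`` additionally
    get a ``differentiation_outlier`` flag.
    """
    clean: dict[str, set[str]] = {}
    for name, ids in lists.items():
        ids = set(ids)
        if known_genes is not None:
            unknown = ids - known_genes
            if unknown:
                logger.warning("list %r has %d unknown gene ids (ignored)",
                               name, len(unknown))
            ids &= known_genes
        clean[name] = ids
    gene_ids = links["gene_id"].unique()
    out = pd.DataFrame(index=pd.Index(gene_ids, name="gene_id"))
    for name, ids in clean.items():
        out[name] = out.index.isin(ids)
    if outlier_windows is not None:
        hit = links[links["window"].isin(outlier_windows)]["gene_id"].unique()
        out["differentiation_outlier"] = out.index.isin(hit)
    return out.reset_index()
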