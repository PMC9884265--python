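"""Readers and writers for the plain-text interchange formats.

Supported: layout YAML, BED intervals, bedGraph tracks, gene tables
(6-column BED or simplified GFF3), 4-column pairs text, sparse/dense contact
matrix TSV, BEDPE-like interaction TSV, and FASTA.

BED/bedGraph/pairs coordinates are kept in the package-wide 0-based half-open
convention (BED-native); GFF3 input (1-based, closed) is converted on read.
"""

from __future__ import annotations

import gzip
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import ContactMatrix, GeneAnnotation, GenomeLayout, SignalTrack

__all__ = [
    "read_layout",
    "write_layout",
    "read_bed",
    "write_bed",
    "read_bedgraph_track",
    "write_bedgraph_track",
    "read_genes",
    "write_genes_bed",
    "read_pairs",
    "write_pairs",
    "read_matrix_sparse",
    "write_matrix_sparse",
    "read_matrix_dense",
    "write_matrix_dense",
    "read_interactions",
    "write_interactions",
    "read_fasta",
    "write_fasta",
]


def _open(path, mode="rt"):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


# -- layout -----------------------------------------------------------------


def read_layout(path) -> GenomeLayout:
    """Read a YAML genome layout (chromosomes, pericentromeres, bin size)."""
    with _open(path) as fh:
        cfg = yaml.safe_load(fh)
    chroms = [(c["name"], int(c["length"])) for c in cfg["chromosomes"]]
    peri = {
        c["name"]: tuple(int(x) for x in c["pericentromere"])
        for c in cfg["chromosomes"]
        if c.get("pericentromere")
    }
    return GenomeLayout(tuple(chroms), peri, int(cfg.get("bin_size", 20_000)))


def write_layout(layout: GenomeLayout, path) -> None:
    peri = dict(layout.pericentromere)
    cfg = {
        "bin_size": layout.bin_size,
        "chromosomes": [
            {"name": n, "length": l, **({"pericentromere": list(peri[n])} if n in peri else {})}
            for n, l in layout.chromosomes
        ],
    }
    with _open(path, "wt") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)


# -- intervals --------------------------------------------------------------


def read_bed(path, extra_cols: list[str] | None = None) -> pd.DataFrame:
    names = ["chrom", "start", "end"] + (extra_cols or [])
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df = df.iloc[:, : len(names)]
    df.columns = names[: df.shape[1]]
    return df


def write_bed(df: pd.DataFrame, path, cols: list[str] | None = None) -> None:
    cols = cols or [c for c in df.columns]
    df[cols].to_csv(path, sep="\t", header=False, index=False)


# -- tracks -----------------------------------------------------------------


def read_bedgraph_track(path, layout: GenomeLayout, name: str, bin_size: int | None = None,
                        condition: str | None = None) -> SignalTrack:
    """Read a bedGraph into a binned SignalTrack (intervals must be bin-aligned)."""
    bin_size = bin_size or layout.bin_size
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "start", "end", "value"],
                     comment="#")
    values = {}
    for chrom, length in layout.chromosomes:
        n = -(-length // bin_size)
        v = np.full(n, np.nan)
        sub = df[df["chrom"] == chrom]
        idx = sub["start"].to_numpy() // bin_size
        v[idx] = sub["value"].to_numpy()
        values[chrom] = v
    return SignalTrack(name=name, bin_size=bin_size, values=values, condition=condition)


def write_bedgraph_track(track: SignalTrack, layout: GenomeLayout, path) -> None:
    with _open(path, "wt") as fh:
        for chrom, length in layout.chromosomes:
            v = track.values.get(chrom)
            if v is None:
                continue
            for b, val in enumerate(v):
                if np.isnan(val):
                    continue
                s = b * track.bin_size
                fh.write(f"{chrom}\t{s}\t{min(s + track.bin_size, length)}\t{val:.6g}\n")


# -- genes ------------------------------------------------------------------


def read_genes(path) -> GeneAnnotation:
    """Read genes from 6-column BED or simplified GFF3 (detected per line)."""
    rows = []
    with _open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) >= 8 and f[6] in "+-" and not f[5] in "+-":
                # GFF3: seqid source type start end score strand frame attrs
                if f[2] not in ("gene", "mRNA"):
                    continue
                attrs = dict(kv.split("=", 1) for kv in f[8].split(";") if "=" in kv)
                gid = attrs.get("ID") or attrs.get("gene_id") or f"gene{len(rows)}"
                rows.append((gid, f[0], int(f[3]) - 1, int(f[4]), f[6]))
            else:
                # BED6: chrom start end name score strand
                rows.append((f[3], f[0], int(f[1]), int(f[2]), f[5]))
    return GeneAnnotation(pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand"]))


def write_genes_bed(genes: GeneAnnotation, path) -> None:
    df = genes.df.assign(score=0)[["chrom", "start", "end", "gene_id", "score", "strand"]]
    df.to_csv(path, sep="\t", header=False, index=False)


# -- pairs ------------------------------------------------------------------


def read_pairs(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", header=None,
                       names=["chrom1", "pos1", "chrom2", "pos2"], comment="#")


def write_pairs(pairs: pd.DataFrame, path) -> None:
    pairs[["chrom1", "pos1", "chrom2", "pos2"]].to_csv(path, sep="\t", header=False, index=False)


# -- matrices ---------------------------------------------------------------


def write_matrix_sparse(cm: ContactMatrix, path) -> None:
    """3-column sparse upper-triangle TSV with a ``#chrom`` block per chromosome."""
    with _open(path, "wt") as fh:
        fh.write(f"#assay={cm.assay}\tcondition={cm.condition}\tbalanced={int(cm.balanced)}"
                 f"\tbin_size={cm.bin_size}\n")
        for chrom in cm.layout.names:
            m = cm.matrices[chrom]
            fh.write(f"#chrom={chrom}\tn_bins={m.shape[0]}\n")
            iu, ju = np.triu_indices_from(m)
            vals = m[iu, ju]
            keep = ~np.isnan(vals) & (vals != 0)
            for i, j, v in zip(iu[keep], ju[keep], vals[keep]):
                fh.write(f"{i}\t{j}\t{v:.6g}\n")


def read_matrix_sparse(path, layout: GenomeLayout) -> ContactMatrix:
    meta = {"assay": "HiC", "condition": "0h", "balanced": "0"}
    mats = {c: np.zeros((layout.n_bins(c),) * 2) for c in layout.names}
    chrom = None
    with _open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                kv = dict(p.split("=", 1) for p in line[1:].strip().split("\t") if "=" in p)
                if "chrom" in kv:
                    chrom = kv["chrom"]
                else:
                    meta.update(kv)
                continue
            i, j, v = line.split("\t")
            i, j, v = int(i), int(j), float(v)
            mats[chrom][i, j] = v
            mats[chrom][j, i] = v
    return ContactMatrix(layout, mats, assay=meta["assay"], condition=meta["condition"],
                         balanced=bool(int(meta["balanced"])))


def write_matrix_dense(m: np.ndarray, path) -> None:
    np.savetxt(path, m, delimiter="\t", fmt="%.6g")


def read_matrix_dense(path) -> np.ndarray:
    return np.atleast_2d(np.loadtxt(path, delimiter="\t"))


# -- interactions (BEDPE-like) ---------------------------------------------

BEDPE_COLS = [
    "chrom1", "start1", "end1", "chrom2", "start2", "end2",
    "count", "expected", "pvalue", "padj",
]


def write_interactions(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_interactions(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# -- FASTA ------------------------------------------------------------------


def read_fasta(path) -> dict[str, str]:
    from Bio import SeqIO

    with _open(path) as fh:
        return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fh, "fasta")}


def write_fasta(seqs: dict[str, str], path) -> None:
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord
    from Bio import SeqIO

    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    with _open(path, "wt") as fh:
        SeqIO.write(records, fh, "fasta")
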