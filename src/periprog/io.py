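"""Readers and writers for the plain-text interchange formats.

Count matrices travel as MatrixMarket .mtx plus genes/barcodes TSVs (or a
dense genes-as-rows TSV), gene sets as GMT, fragments as the 5-column
BED-like TSV (chrom, start, end, barcode, count; 0-based half-open), peaks
as BED plus a GC TSV, motif annotations as (peak_id, motif_id) pairs.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io as sio
import scipy.sparse as sp

from .atac_scores import FragmentSet, MotifAnnotationMatrix, PeakSet
from .sc_preprocess import CountMatrix

__all__ = [
    "read_count_matrix_mtx", "write_count_matrix_mtx",
    "read_count_matrix_tsv", "write_count_matrix_tsv",
    "read_gmt", "write_gmt",
    "read_fragments", "write_fragments",
    "read_peaks", "write_peaks",
    "read_motif_annotations", "write_motif_annotations",
    "read_grouped_measurements", "read_tracks",
]


def read_count_matrix_mtx(directory: str | Path, sample: str | None = None) -> CountMatrix:
    d = Path(directory)
    X = sp.csr_matrix(sio.mmread(d / "matrix.mtx")).astype(np.int64)
    genes = pd.read_csv(d / "genes.tsv", sep="\t", header=None)[0].to_numpy(dtype=object)
    bc_df = pd.read_csv(d / "barcodes.tsv", sep="\t", header=None)
    barcodes = bc_df[0].to_numpy(dtype=object)
    if bc_df.shape[1] > 1:
        samples = bc_df[1].to_numpy(dtype=object)
    else:
        samples = np.full(len(barcodes), sample or "sample", dtype=object)
    return CountMatrix(X, genes, barcodes, samples)


def write_count_matrix_mtx(m: CountMatrix, directory: str | Path) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    sio.mmwrite(str(d / "matrix.mtx"), sp.coo_matrix(m.X))
    pd.Series(m.gene_ids).to_csv(d / "genes.tsv", sep="\t", header=False, index=False)
    pd.DataFrame({"barcode": m.barcodes, "sample": m.sample_labels}).to_csv(
        d / "barcodes.tsv", sep="\t", header=False, index=False)


def read_count_matrix_tsv(path: str | Path, sample: str = "sample") -> CountMatrix:
    """Dense TSV with genes as rows, barcodes as columns."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return CountMatrix(sp.csr_matrix(df.to_numpy(dtype=np.int64)),
                       df.index.to_numpy(dtype=object),
                       df.columns.to_numpy(dtype=object),
                       np.full(df.shape[1], sample, dtype=object))


def write_count_matrix_tsv(m: CountMatrix, path: str | Path) -> None:
    pd.DataFrame(np.asarray(m.X.todense()), index=m.gene_ids,
                 columns=m.barcodes).to_csv(path, sep="\t")


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    sets: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        sets[fields[0]] = [g for g in fields[2:] if g]
    return sets


def write_gmt(sets: dict[str, list[str] | set[str]], path: str | Path,
              description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([str(name), description, *sorted(map(str, genes))]) + "\n")


def read_fragments(path: str | Path, genome: dict[str, int] | None = None) -> FragmentSet:
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "start", "end", "barcode", "count"])
    return FragmentSet(df["chrom"].to_numpy(dtype=object),
                       df["start"].to_numpy(), df["end"].to_numpy(),
                       df["barcode"].to_numpy(dtype=object),
                       df["count"].to_numpy(), genome=genome or {})


def write_fragments(f: FragmentSet, path: str | Path) -> None:
    pd.DataFrame({"chrom": f.chrom, "start": f.start, "end": f.end,
                  "barcode": f.barcode, "count": f.count}).to_csv(
        path, sep="\t", header=False, index=False)


def read_peaks(bed_path: str | Path, gc_path: str | Path) -> PeakSet:
    bed = pd.read_csv(bed_path, sep="\t", header=None, names=["chrom", "start", "end"])
    gc = pd.read_csv(gc_path, sep="\t", header=None, names=["peak_id", "gc"])
    return PeakSet(bed["chrom"].to_numpy(dtype=object), bed["start"].to_numpy(),
                   bed["end"].to_numpy(), gc["gc"].to_numpy())


def write_peaks(p: PeakSet, bed_path: str | Path, gc_path: str | Path) -> None:
    pd.DataFrame({"chrom": p.chrom, "start": p.start, "end": p.end}).to_csv(
        bed_path, sep="\t", header=False, index=False)
    pd.DataFrame({"peak_id": p.ids, "gc": p.gc_content}).to_csv(
        gc_path, sep="\t", header=False, index=False)


def read_motif_annotations(path: str | Path, peak_ids: np.ndarray) -> MotifAnnotationMatrix:
    df = pd.read_csv(path, sep="\t", header=None, names=["peak_id", "motif_id"])
    peak_index = {p: i for i, p in enumerate(peak_ids)}
    motif_ids = np.array(sorted(df["motif_id"].unique()), dtype=object)
    motif_index = {m: j for j, m in enumerate(motif_ids)}
    rows = df["peak_id"].map(peak_index)
    if rows.isna().any():
        raise ValueError("motif annotation references unknown peak ids")
    cols = df["motif_id"].map(motif_index)
    M = sp.csr_matrix((np.ones(len(df), dtype=bool), (rows, cols)),
                      shape=(len(peak_ids), len(motif_ids)))
    return MotifAnnotationMatrix(M, motif_ids)


def write_motif_annotations(ma: MotifAnnotationMatrix, peak_ids: np.ndarray,
                            path: str | Path) -> None:
    coo = sp.coo_matrix(ma.membership)
    pd.DataFrame({"peak_id": np.asarray(peak_ids)[coo.row],
                  "motif_id": ma.motif_ids[coo.col]}).to_csv(
        path, sep="\t", header=False, index=False)


def read_grouped_measurements(path: str | Path) -> dict[str, list[float]]:
    """CSV with columns (group, value) -> group -> measurement list."""
    df = pd.read_csv(path)
    return {str(g): sub["value"].astype(float).tolist()
            for g, sub in df.groupby(df.columns[0])}


def read_tracks(path: str | Path) -> list:
    """CSV with columns (id, condition, t, x, y) -> MigrationTrack list."""
    from .cohort_stats import MigrationTrack

    df = pd.read_csv(path)
    tracks = []
    for (oid, cond), sub in df.groupby(["id", "condition"], sort=False):
        sub = sub.sort_values("t")
        tracks.append(MigrationTrack(str(oid), str(cond), sub["t"].to_numpy(),
                                     sub["x"].to_numpy(), sub["y"].to_numpy()))
    return tracks
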