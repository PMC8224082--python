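"""Reading and writing the pipeline's file formats.

Images travel as multi-page TIFF (one page per channel, 16-bit) with the
channel names and the pixel size in the TIFF's shaped metadata; tables as
CSV/TSV with header rows.  Genomic inputs are BED6 (0-based half-open) or
GFF3 (converted to 0-based half-open on read).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .chip import GeneCountTable, GeneModel
from .qpcr import CtTable
from .segmentation import NucleusField

__all__ = [
    "write_image_field",
    "read_image_field",
    "write_labels",
    "read_labels",
    "read_reads_bed",
    "read_genes_bed",
    "read_genes_gff3",
    "write_count_table",
    "read_count_table",
    "read_ct_table",
]

BED6_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


def write_image_field(field: NucleusField, path: str | Path) -> None:
    """Write channels as a multi-page 16-bit TIFF with sidecar metadata."""
    names = list(field.channels)
    stack = np.stack([field.channels[n] for n in names])
    stack = np.clip(np.round(stack), 0, np.iinfo(np.uint16).max).astype(np.uint16)
    tifffile.imwrite(
        path,
        stack,
        photometric="minisblack",
        metadata={"axes": "CYX", "channel_names": names, "pixel_size_um": field.pixel_size_um},
    )


def read_image_field(path: str | Path, pixel_size_um: float | None = None) -> NucleusField:
    """Read a multi-page TIFF written by :func:`write_image_field`.

    ``pixel_size_um`` overrides (or supplies, for foreign TIFFs without the
    metadata entry) the physical pixel size.
    """
    with tifffile.TiffFile(path) as tf:
        stack = tf.asarray()
        meta = tf.shaped_metadata[0] if tf.shaped_metadata else {}
    if stack.ndim == 2:
        stack = stack[None]
    names = meta.get("channel_names", [f"channel_{i}" for i in range(stack.shape[0])])
    px = pixel_size_um if pixel_size_um is not None else meta.get("pixel_size_um")
    if px is None:
        raise ValueError("pixel size not in TIFF metadata; pass pixel_size_um")
    channels = {name: stack[i].astype(float) for i, name in enumerate(names)}
    return NucleusField(channels=channels, pixel_size_um=float(px))


def write_labels(labels: np.ndarray, path: str | Path, pixel_size_um: float | None = None) -> None:
    meta = {"pixel_size_um": pixel_size_um} if pixel_size_um is not None else {}
    tifffile.imwrite(path, labels.astype(np.uint16), metadata=meta)


def read_labels(path: str | Path) -> np.ndarray:
    return tifffile.imread(path).astype(np.int32)


def read_reads_bed(path: str | Path) -> pd.DataFrame:
    """Aligned read intervals from BED3+/BED6 (0-based half-open)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df.columns = BED6_COLUMNS[: df.shape[1]]
    return df


def read_genes_bed(path: str | Path) -> list[GeneModel]:
    """Gene models from BED6; the name field is the gene id."""
    df = read_reads_bed(path)
    if "name" not in df.columns:
        df["name"] = [f"gene_{i}" for i in range(len(df))]
    if "strand" not in df.columns:
        df["strand"] = "."
    return [
        GeneModel(gene_id=str(r.name_), chrom=str(r.chrom), start=int(r.start), end=int(r.end), strand=str(r.strand))
        for r in df.rename(columns={"name": "name_"}).itertuples(index=False)
    ]


def read_genes_gff3(path: str | Path, feature_type: str = "gene") -> list[GeneModel]:
    """Gene models from GFF3, converted to 0-based half-open coordinates."""
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    genes = []
    for feat in db.features_of_type(feature_type):
        gene_id = feat.attributes.get("ID", [feat.id])[0]
        genes.append(
            GeneModel(
                gene_id=gene_id,
                chrom=feat.seqid,
                start=feat.start - 1,  # GFF3 is 1-based closed
                end=feat.end,
                strand=feat.strand or ".",
            )
        )
    return genes


def write_count_table(table: GeneCountTable, counts_path: str | Path, samples_path: str | Path) -> None:
    out = table.counts.copy()
    if table.gene_lengths is not None:
        out.insert(0, "length_bp", table.gene_lengths)
    out.to_csv(counts_path, sep="\t", index_label="gene_id")
    table.sample_info.to_csv(samples_path, sep="\t", index_label="sample")


def read_count_table(counts_path: str | Path, samples_path: str | Path) -> GeneCountTable:
    counts = pd.read_csv(counts_path, sep="\t", index_col="gene_id")
    lengths = None
    if "length_bp" in counts.columns:
        lengths = counts.pop("length_bp")
    samples = pd.read_csv(samples_path, sep="\t", index_col="sample")
    return GeneCountTable(counts=counts, sample_info=samples, gene_lengths=lengths)


def read_ct_table(path: str | Path, reference_gene: str, calibrator_group: str) -> CtTable:
    return CtTable(
        data=pd.read_csv(path),
        reference_gene=reference_gene,
        calibrator_group=calibrator_group,
    )
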