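"""File I/O: TIFF stacks, FASTA/FASTQ, spot/track CSV tables."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "write_stack",
    "read_stack",
    "write_fasta",
    "read_fasta",
    "write_fastq",
    "read_fastq",
    "write_table",
    "read_table",
]


def write_stack(path, image: np.ndarray,
                voxel_xy_nm: float | None = None,
                voxel_z_nm: float | None = None) -> None:
    """Write a (nz, ny, nx) stack as TIFF with voxel size in metadata (um)."""
    meta = {"axes": "ZYX"}
    kwargs = {}
    if voxel_xy_nm:
        px_um = voxel_xy_nm / 1000.0
        kwargs["resolution"] = (1.0 / px_um, 1.0 / px_um)
        meta["unit"] = "um"
    if voxel_z_nm:
        meta["spacing"] = voxel_z_nm / 1000.0
    tifffile.imwrite(path, np.asarray(image, dtype=np.float32),
                     imagej=True, metadata=meta, **kwargs)


def read_stack(path) -> np.ndarray:
    return tifffile.imread(path)


def write_fasta(path, table: pd.DataFrame,
                id_col: str = "id", seq_col: str = "sequence") -> None:
    records = [SeqRecord(Seq(row[seq_col]), id=str(row[id_col]), description="")
               for _, row in table.iterrows()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> pd.DataFrame:
    rows = [{"id": rec.id, "sequence": str(rec.seq).upper()}
            for rec in SeqIO.parse(str(path), "fasta")]
    return pd.DataFrame(rows, columns=["id", "sequence"])


def write_fastq(path, reads: pd.DataFrame,
                name_col: str = "name", seq_col: str = "sequence") -> None:
    """Write reads with uniform Phred-33 quality 'I' (Q40)."""
    records = []
    for _, row in reads.iterrows():
        rec = SeqRecord(Seq(row[seq_col]), id=str(row[name_col]), description="")
        rec.letter_annotations["phred_quality"] = [40] * len(row[seq_col])
        records.append(rec)
    SeqIO.write(records, str(path), "fastq")


def read_fastq(path) -> pd.DataFrame:
    rows = [{"name": rec.id, "sequence": str(rec.seq).upper()}
            for rec in SeqIO.parse(str(path), "fastq")]
    return pd.DataFrame(rows, columns=["name", "sequence"])


def write_table(path, table: pd.DataFrame) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path)
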