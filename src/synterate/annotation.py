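"""Genome annotation container and flat-file formats.

A :class:`GenomeAnnotation` holds the per-replicon gene layout used
throughout the analysis: gene coordinates (0-based half-open), strand,
rRNA flags, replicon length/circularity, the replication origin when
known, and the radiation-resistance label (R/N).  Annotations round-trip
through a simple TSV format and can be read from GFF3.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

__all__ = ["GenomeAnnotation", "read_annotation_tsv", "read_annotation_gff3"]

GENE_COLUMNS = ["gene_id", "start", "end", "strand", "is_rrna"]


@dataclass
class GenomeAnnotation:
    """Gene layout of one replicon.

    ``genes`` is a DataFrame with columns ``gene_id, start, end, strand,
    is_rrna``, sorted by ``start``; coordinates are 0-based half-open
    and ``strand`` is "+" or "-".
    """

    replicon_id: str
    length: int
    circular: bool = True
    oric: Optional[int] = None
    genes: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=GENE_COLUMNS))
    resistance: str = "N"

    def __post_init__(self):
        g = self.genes
        if len(g):
            if not ((g["start"] >= 0) & (g["start"] < g["end"]) & (g["end"] <= self.length)).all():
                raise ValueError("gene coordinates must satisfy 0 <= start < end <= length")
            if g["gene_id"].duplicated().any():
                raise ValueError("duplicate gene ids")
            self.genes = g.sort_values("start", kind="stable").reset_index(drop=True)
        if self.oric is not None and not (0 <= self.oric < self.length):
            raise ValueError("oriC must lie within the replicon")
        if self.resistance not in ("R", "N"):
            raise ValueError("resistance label must be 'R' or 'N'")

    def __len__(self) -> int:
        return len(self.genes)

    @property
    def n_rrna(self) -> int:
        return int(self.genes["is_rrna"].sum()) if len(self.genes) else 0

    def gene_ranks(self) -> pd.DataFrame:
        """gene_id -> rank (0..n-1 along the replicon) and strand."""
        out = self.genes[["gene_id", "strand"]].copy()
        out["rank"] = range(len(out))
        return out.set_index("gene_id")

    # ------------------------------------------------------------------
    def to_tsv(self, path: str | Path) -> None:
        path = Path(path)
        with path.open("w") as fh:
            fh.write(f"#replicon={self.replicon_id}\tlength={self.length}"
                     f"\tcircular={int(self.circular)}"
                     f"\toric={'' if self.oric is None else self.oric}"
                     f"\tresistance={self.resistance}\n")
            self.genes.to_csv(fh, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GenomeAnnotation":
        return read_annotation_tsv(path)


def read_annotation_tsv(path: str | Path) -> GenomeAnnotation:
    path = Path(path)
    text = path.read_text()
    header, _, body = text.partition("\n")
    if not header.startswith("#"):
        raise ValueError(f"{path}: missing '#replicon=...' header line")
    meta = dict(item.split("=", 1) for item in header.lstrip("#").split("\t"))
    genes = pd.read_csv(io.StringIO(body), sep="\t",
                        dtype={"gene_id": str, "strand": str})
    genes["is_rrna"] = genes["is_rrna"].astype(bool)
    oric = meta.get("oric", "")
    return GenomeAnnotation(
        replicon_id=meta["replicon"],
        length=int(meta["length"]),
        circular=bool(int(meta.get("circular", "1"))),
        oric=None if oric == "" else int(oric),
        genes=genes,
        resistance=meta.get("resistance", "N"),
    )


def read_annotation_gff3(path: str | Path, replicon_id: str | None = None,
                         length: int | None = None, circular: bool = True,
                         oric: int | None = None,
                         resistance: str = "N") -> GenomeAnnotation:
    """Build an annotation from a GFF3 file (gene / rRNA features).

    GFF3 is 1-based inclusive; coordinates are converted to 0-based
    half-open.  The rRNA flag is set for rRNA-typed features or those
    carrying an ``rRNA`` attribute.
    """
    rows = []
    seqid_seen = None
    region_len = length
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 9:
            continue
        seqid, _source, ftype, start, end, _score, strand, _phase, attrs = parts[:9]
        if ftype == "region" and region_len is None:
            region_len = int(end)
        if ftype not in ("gene", "rRNA", "CDS"):
            continue
        if replicon_id is not None and seqid != replicon_id:
            continue
        seqid_seen = seqid
        attr = dict(kv.split("=", 1) for kv in attrs.split(";") if "=" in kv)
        rows.append({
            "gene_id": attr.get("ID", f"{seqid}:{start}-{end}"),
            "start": int(start) - 1,
            "end": int(end),
            "strand": strand,
            "is_rrna": ftype == "rRNA" or attr.get("rRNA", "").lower() in ("1", "true"),
        })
    genes = pd.DataFrame(rows, columns=GENE_COLUMNS).drop_duplicates("gene_id")
    if region_len is None:
        region_len = int(genes["end"].max()) if len(genes) else 0
    return GenomeAnnotation(
        replicon_id=replicon_id or seqid_seen or Path(path).stem,
        length=region_len, circular=circular, oric=oric,
        genes=genes, resistance=resistance,
    )
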