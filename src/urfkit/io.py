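"""Sequence and annotation I/O.

FASTA goes through Bio.SeqIO, GFF3 through gffutils, BED and all tabular
products through pandas. Internally every interval is 0-based half-open;
GFF3 is converted from/to its native 1-based closed convention on the way
in and out. Tables are written as TSV with ``.`` for missing values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("urfkit")

_ALLOWED = set("ACGTN-")


@dataclass
class SeqRecordMeta:
    """A named DNA sequence with provenance metadata."""

    id: str
    sequence: str
    individual: str = ""
    circular: bool = False

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper().replace("U", "T")
        if not self.sequence:
            raise ValueError(f"record {self.id!r}: empty sequence")
        bad = set(self.sequence) - _ALLOWED
        if bad:
            raise ValueError(
                f"record {self.id!r}: illegal characters {sorted(bad)} "
                "(alphabet is A/C/G/T/N/-)"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class Feature:
    name: str
    type: str  # gene | rRNA | URF | intergenic
    start: int  # 0-based half-open
    end: int
    strand: str = "+"

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class AnnotationSet:
    """Features on one genome, kept sorted by start coordinate."""

    seqid: str
    features: list[Feature] = field(default_factory=list)
    seq_length: int | None = None

    def __post_init__(self) -> None:
        self.features.sort(key=lambda f: (f.start, f.end))
        for f in self.features:
            if f.start < 0 or f.end <= f.start:
                raise ValueError(f"feature {f.name!r}: bad interval ({f.start},{f.end})")
            if self.seq_length is not None and f.end > self.seq_length:
                raise ValueError(
                    f"feature {f.name!r} ends at {f.end}, beyond sequence "
                    f"length {self.seq_length}"
                )

    def of_type(self, *types: str) -> list[Feature]:
        return [f for f in self.features if f.type in types]


def read_fasta(path: str | Path) -> list[SeqRecordMeta]:
    """Read a FASTA file; duplicate ids are an error, empty files a warning."""
    records = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        records.append(SeqRecordMeta(id=rec.id, sequence=str(rec.seq), individual=rec.id))
    if not records:
        logger.warning("%s: no FASTA records found", path)
    return records


def write_fasta(records: list[SeqRecordMeta], path: str | Path) -> None:
    SeqIO.write(
        [SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records],
        str(path),
        "fasta",
    )


def read_annotations(path: str | Path) -> AnnotationSet:
    """Read GFF3 or BED annotations (dispatch on file extension)."""
    path = Path(path)
    if path.suffix.lower() == ".bed":
        return _read_bed(path)
    return _read_gff3(path)


def _read_gff3(path: Path) -> AnnotationSet:
    if path.stat().st_size == 0:
        logger.warning("%s: empty annotation file", path)
        return AnnotationSet(seqid="", features=[])
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    feats, seqid = [], ""
    for f in db.all_features():
        seqid = f.seqid
        name = f.attributes.get("Name", f.attributes.get("ID", [f.id]))[0]
        # GFF3 is 1-based closed; internal is 0-based half-open
        feats.append(Feature(name=name, type=f.featuretype, start=f.start - 1, end=f.end, strand=f.strand or "+"))
    return AnnotationSet(seqid=seqid, features=feats)


def _read_bed(path: Path) -> AnnotationSet:
    if path.stat().st_size == 0:
        logger.warning("%s: empty annotation file", path)
        return AnnotationSet(seqid="", features=[])
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    feats = []
    seqid = str(df.iloc[0, 0])
    for _, row in df.iterrows():
        name = str(row[3]) if len(row) > 3 else f"feature_{row[1]}"
        strand = str(row[5]) if len(row) > 5 else "+"
        feats.append(Feature(name=name, type="gene", start=int(row[1]), end=int(row[2]), strand=strand))
    return AnnotationSet(seqid=seqid, features=feats)


def write_gff3(annotations: AnnotationSet, path: str | Path, source: str = "urfkit") -> None:
    lines = ["##gff-version 3"]
    for f in annotations.features:
        lines.append(
            "\t".join(
                [
                    annotations.seqid,
                    source,
                    f.type,
                    str(f.start + 1),  # back to 1-based closed
                    str(f.end),
                    ".",
                    f.strand,
                    ".",
                    f"ID={f.name};Name={f.name}",
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_bed(annotations: AnnotationSet, path: str | Path) -> None:
    lines = [
        f"{annotations.seqid}\t{f.start}\t{f.end}\t{f.name}\t0\t{f.strand}"
        for f in annotations.features
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    """Write the package's single tabular dialect: TSV, header, '.' for NA."""
    df.to_csv(path, sep="\t", index=False, na_rep=".", float_format="%.6g")


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["."])


def sha256_of(path: str | Path) -> str:
    import hashlib

    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()
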