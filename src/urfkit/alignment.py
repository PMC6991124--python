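"""Multi-individual locus alignments.

A :class:`LocusAlignment` holds the aligned copies of one locus across the
sampled individuals of a species, together with its coding status and, for
coding loci, the reading frame and strand. All diversity and codon-usage
statistics operate on this container.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .codes import codon_indices, reverse_complement, seq_to_ints

STATUSES = ("coding", "noncoding", "test")


@dataclass
class LocusAlignment:
    """Gap-aware alignment of one locus across N individuals.

    ``frame`` is the offset (0/1/2) of codon position 1 relative to the
    alignment start *on the coding strand*; for minus-strand loci rows are
    reverse-complemented before codon extraction.
    """

    locus_name: str
    rows: dict[str, str]  # individual -> aligned sequence
    status: str = "test"
    frame: int = 0
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.status not in STATUSES:
            raise ValueError(f"status must be one of {STATUSES}, got {self.status!r}")
        if self.frame not in (0, 1, 2):
            raise ValueError("frame must be 0, 1 or 2")
        lengths = {len(s) for s in self.rows.values()}
        if len(lengths) > 1:
            raise ValueError(
                f"{self.locus_name}: rows have unequal aligned lengths {sorted(lengths)}"
            )
        self.rows = {k: v.upper() for k, v in self.rows.items()}

    @property
    def individuals(self) -> list[str]:
        return list(self.rows)

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def length(self) -> int:
        return len(next(iter(self.rows.values())))

    def oriented_rows(self) -> dict[str, str]:
        """Rows on the coding strand (reverse-complemented if strand is '-')."""
        if self.strand == "-":
            return {k: reverse_complement(v) for k, v in self.rows.items()}
        return self.rows

    def nuc_matrix(self) -> np.ndarray:
        """(n_rows, length) int8 matrix in alignment orientation."""
        return np.stack([seq_to_ints(s) for s in self.rows.values()])

    def codon_matrix(self) -> np.ndarray:
        """(n_rows, n_codons) full 64-space codon indices on the coding strand.

        Codon columns containing gaps or N in a row get -1 in that row.
        """
        oriented = self.oriented_rows()
        mat = np.stack([seq_to_ints(s) for s in oriented.values()])
        return codon_indices(mat, frame=self.frame)

    def subset(self, individuals: list[str]) -> "LocusAlignment":
        return LocusAlignment(
            locus_name=self.locus_name,
            rows={k: self.rows[k] for k in individuals},
            status=self.status,
            frame=self.frame,
            strand=self.strand,
        )


def alignment_from_records(
    records, locus_name: str, status: str = "test", frame: int = 0, strand: str = "+"
) -> LocusAlignment:
    """Build a LocusAlignment from a list of SeqRecordMeta (e.g. one FASTA)."""
    rows = {r.individual or r.id: r.sequence for r in records}
    if len(rows) != len(records):
        raise ValueError(f"{locus_name}: duplicate individual ids in alignment")
    return LocusAlignment(locus_name=locus_name, rows=rows, status=status, frame=frame, strand=strand)
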