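"""Open reading frame discovery, on single sequences and across individuals.

An ORF is a span from a start codon to the first in-frame stop codon, with
the terminal stop included in the span (so a span of 3k nucleotides encodes
k-1 amino acids). Discovery scans both strands, optionally wraps the origin
of circular sequences, and by default requires an ATG start; the full
alternative start set of the genetic code can be enabled.

``conserved_orfs`` implements the multi-individual rule used to delimit
unidentified reading frames: an ORF counts as conserved only if the same
aligned span is an intact ORF (start codon present, no internal stops) in
every individual, and among nested conserved ORFs sharing a stop codon only
the largest is reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .alignment import LocusAlignment
from .codes import ALL_CODONS, GeneticCode, codon_indices, reverse_complement, seq_to_ints
from .io import SeqRecordMeta


@dataclass(frozen=True)
class Orf:
    """0-based half-open span on the source sequence; ``end`` may exceed the
    sequence length for ORFs wrapping the origin of a circular sequence."""

    start: int
    end: int
    strand: str
    frame: int

    @property
    def length_nt(self) -> int:
        return self.end - self.start

    @property
    def length_aa(self) -> int:
        return self.length_nt // 3 - 1


def _start_indices(code: GeneticCode, start_codons) -> np.ndarray:
    return np.array(sorted(ALL_CODONS.index(c) for c in start_codons), dtype=np.int64)


def _scan_one_strand(nuc: np.ndarray, code: GeneticCode, min_len_nt: int,
                     start_idx: np.ndarray, max_start: int, max_len: int) -> list[tuple[int, int]]:
    """All (start_nt, end_nt) ORF spans on one already-oriented sequence.

    Only spans starting before ``max_start`` and no longer than ``max_len``
    are kept (used for the doubled-sequence circular scan).
    """
    spans = []
    is_stop = code.is_stop
    for frame in range(3):
        cods = codon_indices(nuc, frame=frame)
        stop_pos = np.flatnonzero((cods >= 0) & is_stop[cods])
        valid = cods >= 0
        starts = np.flatnonzero(valid & np.isin(cods, start_idx))
        if starts.size == 0:
            continue
        nxt = np.searchsorted(stop_pos, starts)  # first stop at codon index > start
        for s, k in zip(starts, nxt):
            if k >= stop_pos.size:
                continue  # open-ended: no in-frame stop
            e = stop_pos[k]
            start_nt = frame + 3 * int(s)
            end_nt = frame + 3 * (int(e) + 1)
            if start_nt >= max_start or end_nt - start_nt > max_len:
                continue
            if end_nt - start_nt >= min_len_nt:
                spans.append((start_nt, end_nt))
    return spans


def find_orfs(
    seq: SeqRecordMeta | str,
    code: GeneticCode,
    min_len_nt: int = 3,
    start_codons=("ATG",),
    alternative_starts: bool = False,
    strands: str = "both",
    longest_per_stop: bool = False,
) -> list[Orf]:
    """Find ORFs on one sequence.

    By default one ORF is reported per start codon (every start up to the
    shared first in-frame stop); with ``longest_per_stop`` only the largest
    ORF ending at each stop is kept. ``alternative_starts`` switches from
    ATG-only to the genetic code's full start set. Circularity is taken from
    the record's ``circular`` flag: the scan runs on the doubled sequence and
    spans longer than the sequence itself are rejected.
    """
    if min_len_nt < 3:
        raise ValueError("min_len_nt must be >= 3")
    if isinstance(seq, SeqRecordMeta):
        s, circular = seq.sequence, seq.circular
    else:
        s, circular = str(seq).upper(), False
    if "-" in s:
        raise ValueError("find_orfs requires an ungapped sequence")
    L = len(s)
    starts = code.start_codons if alternative_starts else frozenset(start_codons)
    start_idx = _start_indices(code, starts)

    scan_seq = s + s if circular else s
    max_start = L if circular else len(scan_seq)
    orfs: list[Orf] = []
    strand_list = {"both": "+-", "forward": "+", "reverse": "-"}[strands]
    for strand in strand_list:
        oriented = scan_seq if strand == "+" else reverse_complement(scan_seq)
        nuc = seq_to_ints(oriented)
        for a, b in _scan_one_strand(nuc, code, min_len_nt, start_idx, max_start, L):
            if strand == "+":
                f_start, f_end = a, b
            else:
                # map from the reverse-complement back onto forward coordinates
                n = len(scan_seq)
                f_start, f_end = n - b, n - a
                if circular:
                    shift = (f_start // L) * L
                    f_start, f_end = f_start - shift, f_end - shift
            orfs.append(Orf(start=f_start, end=f_end, strand=strand, frame=f_start % 3))
    orfs = sorted(set(orfs), key=lambda o: (o.start, o.end, o.strand))
    if longest_per_stop:
        orfs = _longest_per_stop(orfs)
    return orfs


def _stop_anchor(o: Orf) -> tuple:
    return (o.strand, o.end if o.strand == "+" else o.start)


def _longest_per_stop(orfs: list[Orf]) -> list[Orf]:
    best: dict[tuple, Orf] = {}
    for o in sorted(orfs, key=lambda o: (-o.length_nt, o.start)):
        best.setdefault(_stop_anchor(o), o)
    return sorted(best.values(), key=lambda o: (o.start, o.end, o.strand))


def conserved_orfs(
    alignment: LocusAlignment | dict[str, str],
    code: GeneticCode,
    min_len_nt: int = 3,
    start_codons=("ATG",),
    alternative_starts: bool = False,
) -> list[Orf]:
    """ORFs intact in *every* individual of a whole-genome alignment.

    Returned coordinates are alignment columns. Among conserved ORFs sharing
    a terminal stop only the largest is reported; exact-length ties break to
    the leftmost start.
    """
    rows = alignment.rows if isinstance(alignment, LocusAlignment) else dict(alignment)
    if len(rows) < 2:
        raise ValueError("conserved_orfs needs at least 2 aligned individuals")
    lengths = {len(v) for v in rows.values()}
    if len(lengths) > 1:
        raise ValueError(f"aligned rows have unequal lengths {sorted(lengths)}")

    shared: set[tuple[int, int, str]] | None = None
    for seq in rows.values():
        cols = np.flatnonzero(np.frombuffer(seq.encode(), dtype=np.uint8) != ord("-"))
        ungapped = seq.replace("-", "")
        spans = set()
        for o in find_orfs(ungapped, code, min_len_nt, start_codons=start_codons,
                           alternative_starts=alternative_starts):
            a = int(cols[o.start])
            b = int(cols[o.end - 1]) + 1
            spans.add((a, b, o.strand))
        shared = spans if shared is None else shared & spans

    orfs = [Orf(start=a, end=b, strand=st, frame=a % 3) for a, b, st in (shared or set())]
    return _longest_per_stop(sorted(orfs, key=lambda o: (o.start, o.end, o.strand)))
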