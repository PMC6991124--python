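"""Genetic codes and translation.

Codon count vectors throughout the package are indexed by the *sense codons*
of a :class:`GeneticCode` in fixed lexicographic (A < C < G < T) order, so
vectors computed in different runs or processes are directly comparable.
Under the mold/protozoan/coelenterate mitochondrial code (NCBI translation
table 4) TGA encodes tryptophan, leaving TAA and TAG as the only stops and
62 sense codons.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
from Bio.Data import CodonTable

NUCLEOTIDES = "ACGT"
#: integer encoding used in the numeric fast paths: A=0 C=1 G=2 T=3, N=4, gap=5
NUC_TO_INT = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4, "-": 5}
INT_TO_NUC = "ACGTN-"

ALL_CODONS = ["".join(p) for p in product(NUCLEOTIDES, repeat=3)]

#: friendly aliases -> NCBI translation table ids shipped with the package
TABLE_ALIASES = {
    "standard": 1,
    "mold-protozoan-coelenterate": 4,
    "invertebrate-mitochondrial": 5,
}
_SHIPPED_IDS = (1, 4, 5)


class UnknownGeneticCodeError(ValueError):
    pass


@dataclass(frozen=True)
class GeneticCode:
    """A codon -> amino acid map with start/stop sets and fixed codon order.

    Attributes
    ----------
    table_id:
        Canonical name of the table (``"mold-protozoan-coelenterate"`` etc.).
    ncbi_id:
        NCBI translation table number.
    codon_to_aa:
        Map over all 64 DNA triplets; stop codons map to ``"*"``.
    start_codons, stop_codons:
        Sets of triplets.
    sense_codons:
        The non-stop triplets in lexicographic order; codon count vectors are
        ordered by this list.
    """

    table_id: str
    ncbi_id: int
    codon_to_aa: dict[str, str]
    start_codons: frozenset[str]
    stop_codons: frozenset[str]
    sense_codons: tuple[str, ...]
    _cache: dict = field(default_factory=dict, repr=False, compare=False, hash=False)

    def __post_init__(self) -> None:
        if len(self.codon_to_aa) != 64:
            raise ValueError("genetic code must map all 64 triplets")

    @property
    def n_sense(self) -> int:
        return len(self.sense_codons)

    # ---- numeric helper tables (built lazily, cached on the instance) ----

    @property
    def is_stop(self) -> np.ndarray:
        """Boolean vector over the 64 lexicographic codon indices."""
        if "is_stop" not in self._cache:
            arr = np.array([c in self.stop_codons for c in ALL_CODONS])
            self._cache["is_stop"] = arr
        return self._cache["is_stop"]

    @property
    def aa_codes(self) -> np.ndarray:
        """Amino-acid symbol (as byte ordinal) per 64-codon index; ``*`` for stops."""
        if "aa_codes" not in self._cache:
            self._cache["aa_codes"] = np.array(
                [ord(self.codon_to_aa[c]) for c in ALL_CODONS], dtype=np.int16
            )
        return self._cache["aa_codes"]

    @property
    def full_to_sense(self) -> np.ndarray:
        """Map 64-codon index -> sense-codon index, -1 for stops."""
        if "full_to_sense" not in self._cache:
            arr = np.full(64, -1, dtype=np.int64)
            for i, c in enumerate(self.sense_codons):
                arr[ALL_CODONS.index(c)] = i
            self._cache["full_to_sense"] = arr
        return self._cache["full_to_sense"]

    def translate_codon(self, codon: str) -> str:
        codon = codon.upper().replace("U", "T")
        if any(b not in NUCLEOTIDES for b in codon):
            return "X"
        return self.codon_to_aa[codon]


def available_tables() -> list[str]:
    return sorted(TABLE_ALIASES) + [str(i) for i in _SHIPPED_IDS]


def load_genetic_code(table_id: str | int = "mold-protozoan-coelenterate") -> GeneticCode:
    """Load a shipped genetic code by alias or NCBI table number.

    Raises
    ------
    UnknownGeneticCodeError
        If *table_id* is not among the shipped tables; the message lists the
        valid identifiers.
    """
    if isinstance(table_id, str) and table_id in TABLE_ALIASES:
        name, ncbi_id = table_id, TABLE_ALIASES[table_id]
    else:
        try:
            ncbi_id = int(table_id)
        except (TypeError, ValueError):
            ncbi_id = -1
        if ncbi_id not in _SHIPPED_IDS:
            raise UnknownGeneticCodeError(
                f"unknown genetic code {table_id!r}; available tables: "
                + ", ".join(available_tables())
            )
        name = {v: k for k, v in TABLE_ALIASES.items()}[ncbi_id]

    bio = CodonTable.unambiguous_dna_by_id[ncbi_id]
    codon_to_aa = dict(bio.forward_table)
    for stop in bio.stop_codons:
        codon_to_aa[stop] = "*"
    sense = tuple(c for c in ALL_CODONS if c not in bio.stop_codons)
    return GeneticCode(
        table_id=name,
        ncbi_id=ncbi_id,
        codon_to_aa=codon_to_aa,
        start_codons=frozenset(bio.start_codons),
        stop_codons=frozenset(bio.stop_codons),
        sense_codons=sense,
    )


def translate(seq: str, code: GeneticCode) -> str:
    """Translate an in-frame, gap-free DNA sequence; codons with N become X."""
    seq = seq.upper().replace("U", "T")
    if len(seq) % 3 != 0:
        raise ValueError(f"sequence length {len(seq)} is not a multiple of 3")
    if "-" in seq:
        raise ValueError("cannot translate a gapped sequence")
    return "".join(code.translate_codon(seq[i : i + 3]) for i in range(0, len(seq), 3))


_COMPLEMENT = str.maketrans("ACGTNacgtn-", "TGCANtgcan-")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def seq_to_ints(seq: str) -> np.ndarray:
    """Encode a DNA string as int8 (A=0 C=1 G=2 T=3, N=4, gap=5)."""
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    out = np.full(arr.shape, 4, dtype=np.int8)
    for base, i in NUC_TO_INT.items():
        out[arr == ord(base)] = i
    return out


def ints_to_seq(arr: np.ndarray) -> str:
    return "".join(INT_TO_NUC[i] for i in arr)


def codon_indices(nuc_ints: np.ndarray, frame: int = 0) -> np.ndarray:
    """Full 64-space codon indices from an integer nucleotide array.

    Codons containing anything other than A/C/G/T get index -1. A trailing
    partial codon is dropped. Works on the last axis, so a whole stack of
    simulated sequences can be converted at once.
    """
    nuc_ints = nuc_ints[..., frame:]
    n_codons = nuc_ints.shape[-1] // 3
    trimmed = nuc_ints[..., : n_codons * 3]
    shape = trimmed.shape[:-1] + (n_codons, 3)
    cods = trimmed.reshape(shape).astype(np.int64)
    valid = (cods < 4).all(axis=-1)
    idx = cods[..., 0] * 16 + cods[..., 1] * 4 + cods[..., 2]
    idx[~valid] = -1
    return idx
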