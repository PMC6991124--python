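"""Base composition and codon-usage statistics."""

from __future__ import annotations

import logging
from itertools import combinations

import numpy as np
import pandas as pd

from .alignment import LocusAlignment
from .codes import GeneticCode, seq_to_ints

logger = logging.getLogger("urfkit")


def gc_content(seq) -> float:
    """(G+C)/(A+C+G+T); gaps and N are excluded from the denominator."""
    s = seq.sequence if hasattr(seq, "sequence") else str(seq)
    if not s:
        raise ValueError("empty sequence")
    arr = seq_to_ints(s)
    acgt = np.count_nonzero(arr < 4)
    if acgt == 0:
        raise ValueError("no unambiguous A/C/G/T bases in sequence")
    gc = np.count_nonzero((arr == 1) | (arr == 2))
    return gc / acgt


def pairwise_divergence(alignment: LocusAlignment | dict[str, str]) -> float:
    """Mean between-individual per-site mismatch fraction.

    Columns containing a gap or N in either member of a pair are excluded
    for that pair only, so the statistic uses every column comparable
    between at least the two rows being compared.
    """
    rows = alignment.rows if isinstance(alignment, LocusAlignment) else dict(alignment)
    if len(rows) < 2:
        raise ValueError("pairwise_divergence needs at least 2 rows")
    mats = {k: seq_to_ints(v) for k, v in rows.items()}
    dists = []
    for a, b in combinations(rows, 2):
        x, y = mats[a], mats[b]
        ok = (x < 4) & (y < 4)
        n = int(ok.sum())
        if n == 0:
            continue
        dists.append(np.count_nonzero(x[ok] != y[ok]) / n)
    if not dists:
        raise ValueError("no pairwise-comparable columns in alignment")
    return float(np.mean(dists))


def codon_usage(loci: list[LocusAlignment], code: GeneticCode) -> pd.DataFrame:
    """Relative sense-codon frequencies per locus and individual.

    Returns a tidy table with one row per (locus, individual, codon); the
    62 frequencies of each (locus, individual) sum to 1. Loci shorter than
    one codon are skipped with a warning.
    """
    sense = np.asarray(code.sense_codons)
    out = []
    for loc in loci:
        cods = loc.codon_matrix()
        if cods.shape[1] < 1:
            logger.warning("locus %s shorter than one codon; skipped", loc.locus_name)
            continue
        f2s = code.full_to_sense
        for ind, row in zip(loc.individuals, cods):
            valid = row[(row >= 0) & (f2s[row] >= 0)]
            counts = np.bincount(f2s[valid], minlength=code.n_sense)
            total = counts.sum()
            if total == 0:
                logger.warning("locus %s/%s has no countable codons; skipped",
                               loc.locus_name, ind)
                continue
            freqs = counts / total
            out.append(pd.DataFrame({
                "locus": loc.locus_name,
                "individual": ind,
                "codon": sense,
                "frequency": freqs,
                "n_codons": total,
            }))
    if not out:
        return pd.DataFrame(columns=["locus", "individual", "codon", "frequency", "n_codons"])
    return pd.concat(out, ignore_index=True)
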