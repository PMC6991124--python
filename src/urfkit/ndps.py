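"""Nucleotide Diversity Permutation Simulation (NDPS).

The question: is an observed piN/piS < 1 evidence of purifying selection,
or could neutral mutation alone produce a value that low? The null model
keeps everything about the observed alignment fixed — ancestor, number of
individuals, and the number of mutations carried by each lineage — and only
randomises *where* the mutations land and *what* they change to. Each
replicate therefore has the same nucleotide diversity structure as the data
but no selection. The Monte-Carlo p-value is the fraction of valid
replicates (those with piS > 0) whose simulated piN/piS falls below the
observed value; a small p means neutral mutation rarely produces a ratio
that low, i.e. evidence for purifying selection.

Lineage mutation counts are inferred by majority-consensus parsimony: the
ancestor is the column-wise majority base and each polymorphic column
charges one mutation to each individual carrying a minority state. Columns
with a tied majority are resolved by a seeded random choice (and counted in
``n_tied_columns``). Simulated sequences are free to acquire internal stop
codons — the null models the absence of selection — and stop-containing
codons are skipped by the NG86 stop policy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .alignment import LocusAlignment
from .codes import GeneticCode, codon_indices, seq_to_ints
from .diversity import jukes_cantor, ng86_tables, pinpis

logger = logging.getLogger("urfkit")


@dataclass
class MutationSpectrum:
    """Per-lineage mutation counts inferred from an observed alignment."""

    locus_name: str
    ancestor: np.ndarray  # int8 nucleotide array, coding-strand orientation
    counts: dict[str, int]  # individual -> number of inferred mutations
    total_polymorphic_sites: int
    n_tied_columns: int = 0
    frame: int = 0

    @property
    def total_mutations(self) -> int:
        return sum(self.counts.values())


@dataclass
class NDPSResult:
    locus_name: str
    observed_ratio: float
    simulated_ratios: np.ndarray
    n_valid: int
    mc_p: float  # NaN when no valid simulation
    n_simulations: int
    seed: int | None = None
    observed: object = None  # DiversityResult of the input alignment


def infer_mutation_spectrum(
    alignment: LocusAlignment, rng: np.random.Generator | int | None = None
) -> MutationSpectrum:
    """Majority-consensus ancestor and per-lineage mutation counts.

    Requires >= 3 gap-free rows (with two rows the minority lineage is
    unidentifiable). Ties in the column majority are broken by a seeded
    random choice among the tied bases.
    """
    if alignment.n_rows < 3:
        raise ValueError("mutation spectrum needs >= 3 individuals")
    rng = np.random.default_rng(rng)
    oriented = alignment.oriented_rows()
    mat = np.stack([seq_to_ints(s) for s in oriented.values()])
    if (mat >= 4).any():
        raise ValueError(
            f"{alignment.locus_name}: NDPS requires gap- and N-free alignments"
        )
    inds = list(oriented)
    n, L = mat.shape

    # per-column base counts, (L, 4)
    counts = np.stack([(mat == b).sum(axis=0) for b in range(4)], axis=1)
    maxc = counts.max(axis=1)
    is_tie = (counts == maxc[:, None]).sum(axis=1) > 1
    ancestor = counts.argmax(axis=1).astype(np.int8)
    tied_cols = np.flatnonzero(is_tie)
    for col in tied_cols:
        tied_bases = np.flatnonzero(counts[col] == maxc[col])
        ancestor[col] = rng.choice(tied_bases)
    if tied_cols.size:
        logger.info("%s: %d tied consensus column(s) resolved randomly",
                    alignment.locus_name, tied_cols.size)

    muts = {ind: int((mat[i] != ancestor).sum()) for i, ind in enumerate(inds)}
    poly = int(((mat != mat[0]).any(axis=0)).sum())
    return MutationSpectrum(
        locus_name=alignment.locus_name,
        ancestor=ancestor,
        counts=muts,
        total_polymorphic_sites=poly,
        n_tied_columns=int(tied_cols.size),
        frame=alignment.frame,
    )


def simulate_neutral(
    spectrum: MutationSpectrum,
    n_sims: int,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Neutral replicates as an (n_sims, n_individuals, L) int8 array.

    Each replicate starts from the ancestor; each individual receives its
    observed number of mutations at distinct uniform positions, each changed
    to a uniformly chosen different base.
    """
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    rng = np.random.default_rng(rng)
    L = spectrum.ancestor.size
    inds = list(spectrum.counts)
    sims = np.broadcast_to(spectrum.ancestor, (n_sims, len(inds), L)).copy()
    for i, ind in enumerate(inds):
        k = spectrum.counts[ind]
        if k > L:
            raise ValueError(
                f"{spectrum.locus_name}/{ind}: {k} mutations exceed length {L}"
            )
        if k == 0:
            continue
        for s in range(n_sims):
            pos = rng.choice(L, size=k, replace=False)
            shift = rng.integers(1, 4, size=k, dtype=np.int8)
            sims[s, i, pos] = (sims[s, i, pos] + shift) % 4
    return sims


def _ratios_from_sims(
    sims: np.ndarray, code: GeneticCode, frame: int, stop_policy: str = "exclude"
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised piN, piS and ratio for a stack of simulated alignments."""
    tab = ng86_tables(code, stop_policy)
    cods = codon_indices(sims, frame=frame)  # (n_sims, n_rows, n_codons)
    n_sims, n_rows, _ = cods.shape
    dn_pairs, ds_pairs = [], []
    for i in range(n_rows):
        for j in range(i + 1, n_rows):
            a, b = cods[:, i, :], cods[:, j, :]
            ds = tab.diff_s[a, b]
            dn = tab.diff_n[a, b]
            use = ~np.isnan(ds)
            ss = np.where(use, tab.site_s[a], 0.0) + np.where(use, tab.site_s[b], 0.0)
            ns = np.where(use, tab.site_n[a], 0.0) + np.where(use, tab.site_n[b], 0.0)
            s_sites, n_sites = 0.5 * ss.sum(axis=1), 0.5 * ns.sum(axis=1)
            sd = np.where(use, ds, 0.0).sum(axis=1)
            nd = np.where(use, dn, 0.0).sum(axis=1)
            with np.errstate(invalid="ignore", divide="ignore"):
                ds_pairs.append(jukes_cantor(np.where(s_sites > 0, sd / s_sites, np.nan)))
                dn_pairs.append(jukes_cantor(np.where(n_sites > 0, nd / n_sites, np.nan)))
    with np.errstate(invalid="ignore", divide="ignore"):
        piS = np.nanmean(np.stack(ds_pairs), axis=0)
        piN = np.nanmean(np.stack(dn_pairs), axis=0)
        ratio = np.where(piN == 0.0, 0.0, piN / piS)  # piS=0, piN>0 -> inf -> invalid
        ratio = np.where(np.isinf(ratio), np.nan, ratio)
    return piN, piS, ratio


def mc_pvalue(
    observed_ratio: float,
    simulated_ratios: np.ndarray,
    piS: np.ndarray,
    locus_name: str = "",
    n_simulations: int | None = None,
    seed: int | None = None,
) -> NDPSResult:
    """Monte-Carlo p-value: #(valid simulated ratio < observed) / #valid.

    A simulation is valid when its piS > 0 (the ratio is defined); invalid
    simulations are excluded from numerator and denominator alike.
    """
    simulated_ratios = np.asarray(simulated_ratios, dtype=float)
    piS = np.asarray(piS, dtype=float)
    valid = (piS > 0) & np.isfinite(simulated_ratios)
    n_valid = int(valid.sum())
    if n_valid == 0 or not np.isfinite(observed_ratio):
        logger.warning("%s: no valid simulations (or undefined observed ratio); "
                       "Monte-Carlo p-value is NA", locus_name)
        p = float("nan")
    else:
        p = float((simulated_ratios[valid] < observed_ratio).sum() / n_valid)
    return NDPSResult(
        locus_name=locus_name,
        observed_ratio=float(observed_ratio),
        simulated_ratios=simulated_ratios,
        n_valid=n_valid,
        mc_p=p,
        n_simulations=n_simulations if n_simulations is not None else simulated_ratios.size,
        seed=seed,
    )


def ndps_run(
    alignment: LocusAlignment,
    code: GeneticCode,
    n_sims: int = 1000,
    seed: int | None = None,
    stop_policy: str = "exclude",
) -> NDPSResult:
    """Full permutation test for one locus: infer spectrum, simulate the
    neutral null, and compare the observed piN/piS against it."""
    rng = np.random.default_rng(seed)
    observed = pinpis(alignment, code, stop_policy=stop_policy)
    spectrum = infer_mutation_spectrum(alignment, rng)
    sims = simulate_neutral(spectrum, n_sims, rng)
    _, piS, ratios = _ratios_from_sims(sims, code, spectrum.frame, stop_policy)
    result = mc_pvalue(observed.ratio, ratios, piS, locus_name=alignment.locus_name,
                       n_simulations=n_sims, seed=seed)
    result.observed = observed
    return result
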