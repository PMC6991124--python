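"""Nucleotide diversity and synonymous/nonsynonymous diversity (NG86).

``calculate_pi`` is the Nei–Li per-site nucleotide diversity: the average,
over all sequence pairs, of the pairwise mismatch fraction computed over
the columns comparable for that pair (no sample-size correction by default,
matching the "Pi" statistic of DnaSP; a flag enables the n/(n-1) factor).

``ng86_pairwise`` implements the Nei–Gojobori (1986) counting method:
fractional synonymous/nonsynonymous site counts per codon, pathway-averaged
difference counts for codons differing at more than one position, and the
Jukes–Cantor correction d = -(3/4)·ln(1 - (4/3)·p). Two policies govern
mutations that create stop codons:

* ``"exclude"`` (default): changes to stop codons contribute no sites, and
  mutational pathways passing through a stop codon are dropped from the
  pathway average (the remaining pathways are reweighted; codon pairs whose
  pathways are all blocked are skipped entirely). Codon columns where either
  sequence carries a stop codon are likewise skipped — relevant when scoring
  neutrally simulated sequences that are free to acquire stops.
* ``"nonsynonymous"``: changes to and through stop codons count as
  nonsynonymous and per-codon sites renormalise to S+N=3. This reproduces
  the convention of Biopython's ``calculate_dn_ds`` and is kept as an
  independently cross-checkable reference behaviour.

The whole method reduces to table lookups over 64x64 codon-pair arrays, so
scoring the ~10^5 simulated alignments of a permutation run stays cheap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations, permutations

import numpy as np

from .alignment import LocusAlignment
from .codes import ALL_CODONS, GeneticCode

STOP_POLICIES = ("exclude", "nonsynonymous")


# ---------------------------------------------------------------------------
# NG86 lookup tables
# ---------------------------------------------------------------------------

@dataclass
class NG86Tables:
    """Per-code precomputed NG86 arrays (64-space codon indices)."""

    site_s: np.ndarray  # (64,) synonymous sites per codon; NaN for stops
    site_n: np.ndarray  # (64,)
    diff_s: np.ndarray  # (64, 64) pathway-averaged synonymous differences; NaN = skip pair
    diff_n: np.ndarray  # (64, 64)


def _neighbors(codon: str) -> list[tuple[int, str]]:
    out = []
    for pos in range(3):
        for base in "ACGT":
            if base != codon[pos]:
                out.append((pos, codon[:pos] + base + codon[pos + 1:]))
    return out


def _build_tables(code: GeneticCode, stop_policy: str) -> NG86Tables:
    if stop_policy not in STOP_POLICIES:
        raise ValueError(f"stop_policy must be one of {STOP_POLICIES}")
    aa = code.codon_to_aa
    is_stop = {c: c in code.stop_codons for c in ALL_CODONS}

    site_s = np.full(64, np.nan)
    site_n = np.full(64, np.nan)
    for i, codon in enumerate(ALL_CODONS):
        if is_stop[codon]:
            continue
        s = n = 0.0
        for _, nb in _neighbors(codon):
            if is_stop[nb]:
                if stop_policy == "nonsynonymous":
                    n += 1.0
                # "exclude": contributes no site at all
            elif aa[nb] == aa[codon]:
                s += 1.0
            else:
                n += 1.0
        site_s[i] = s / 3.0
        site_n[i] = n / 3.0

    diff_s = np.full((64, 64), np.nan)
    diff_n = np.full((64, 64), np.nan)
    for i, c1 in enumerate(ALL_CODONS):
        if is_stop[c1]:
            continue
        for j, c2 in enumerate(ALL_CODONS):
            if is_stop[c2]:
                continue
            sd_nd = _pathway_average(c1, c2, aa, is_stop, stop_policy)
            if sd_nd is not None:
                diff_s[i, j], diff_n[i, j] = sd_nd
    return NG86Tables(site_s=site_s, site_n=site_n, diff_s=diff_s, diff_n=diff_n)


def _pathway_average(c1: str, c2: str, aa, is_stop, stop_policy: str):
    """Average (syn, nonsyn) difference counts over single-step pathways.

    Returns None when every pathway is blocked by a stop codon under the
    "exclude" policy (the codon pair is then skipped by the caller).
    """
    if c1 == c2:
        return 0.0, 0.0
    diff_pos = [k for k in range(3) if c1[k] != c2[k]]

    def step(a: str, b: str) -> tuple[float, float]:
        # one nucleotide change a->b
        if is_stop[a] or is_stop[b]:
            return (0.0, 1.0)  # only reachable under "nonsynonymous" policy
        return (1.0, 0.0) if aa[a] == aa[b] else (0.0, 1.0)

    paths = []
    for order in permutations(diff_pos):
        cur, sd, nd, blocked = c1, 0.0, 0.0, False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if is_stop[nxt] and stop_policy == "exclude":
                blocked = True
                break
            s_, n_ = step(cur, nxt)
            sd, nd = sd + s_, nd + n_
            cur = nxt
        if not blocked:
            paths.append((sd, nd))
    if not paths:
        return None
    arr = np.asarray(paths)
    return float(arr[:, 0].mean()), float(arr[:, 1].mean())


def ng86_tables(code: GeneticCode, stop_policy: str = "exclude") -> NG86Tables:
    key = ("ng86", stop_policy)
    if key not in code._cache:
        code._cache[key] = _build_tables(code, stop_policy)
    return code._cache[key]


def jukes_cantor(p):
    """JC69 distance; NaN where p >= 3/4 (correction undefined)."""
    p = np.asarray(p, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(p < 0.75, -0.75 * np.log(1.0 - 4.0 * p / 3.0), np.nan)
    return d if d.ndim else float(d)


# ---------------------------------------------------------------------------
# pairwise NG86
# ---------------------------------------------------------------------------

def _codon_index_pair_stats(a: np.ndarray, b: np.ndarray, tab: NG86Tables):
    """Raw (Sd, Nd, S_sites, N_sites) for two codon-index vectors.

    Codons that are invalid (-1), stops, or whose pathway set is empty are
    skipped in both sequences.
    """
    ok = (a >= 0) & (b >= 0)
    a, b = a[ok], b[ok]
    ds = tab.diff_s[a, b]
    use = ~np.isnan(ds)  # drops stop codons and fully blocked pairs
    a, b, ds = a[use], b[use], ds[use]
    dn = tab.diff_n[a, b]
    sd, nd = ds.sum(), dn.sum()
    s_sites = 0.5 * (tab.site_s[a].sum() + tab.site_s[b].sum())
    n_sites = 0.5 * (tab.site_n[a].sum() + tab.site_n[b].sum())
    return sd, nd, s_sites, n_sites


def ng86_pairwise(
    seq_a: str,
    seq_b: str,
    code: GeneticCode,
    stop_policy: str = "exclude",
) -> tuple[float, float, float, float]:
    """NG86 (dN, dS, N_sites, S_sites) for two in-frame gap-free sequences.

    Codons containing N or a gap in either sequence are skipped in both.
    dN or dS is NaN when the JC correction is undefined (p >= 3/4).
    """
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences must have equal length")
    if len(seq_a) % 3 != 0:
        raise ValueError("sequence length must be a multiple of 3")
    from .codes import codon_indices, seq_to_ints

    a = codon_indices(seq_to_ints(seq_a))
    b = codon_indices(seq_to_ints(seq_b))
    tab = ng86_tables(code, stop_policy)
    sd, nd, s_sites, n_sites = _codon_index_pair_stats(a, b, tab)
    if s_sites == 0 or n_sites == 0:
        raise ValueError("no countable synonymous/nonsynonymous sites")
    ps, pn = sd / s_sites, nd / n_sites
    ds, dn = jukes_cantor(ps), jukes_cantor(pn)
    if np.isnan(ds) or np.isnan(dn):
        warnings.warn("proportion of differences >= 3/4; JC correction undefined")
    return float(dn), float(ds), float(n_sites), float(s_sites)


# ---------------------------------------------------------------------------
# diversity statistics over alignments
# ---------------------------------------------------------------------------

@dataclass
class DiversityResult:
    locus_name: str
    pi: float
    piN: float
    piS: float
    ratio: float  # NaN encodes NA (piN > 0 with piS = 0)
    n_sequences: int
    n_sites_compared: float


def _ratio(piN: float, piS: float) -> float:
    if piN == 0.0:
        return 0.0
    if piS == 0.0:
        return float("nan")
    return piN / piS


def calculate_pi(alignment: LocusAlignment | dict[str, str],
                 sample_size_correction: bool = False) -> float:
    """Nei–Li nucleotide diversity: mean pairwise per-site mismatch fraction."""
    if not isinstance(alignment, LocusAlignment):
        alignment = LocusAlignment(locus_name="", rows=dict(alignment))
    if alignment.n_rows < 2:
        raise ValueError("calculate_pi needs at least 2 sequences")
    mat = alignment.nuc_matrix()
    n = alignment.n_rows
    dists = []
    for i, j in combinations(range(n), 2):
        ok = (mat[i] < 4) & (mat[j] < 4)
        m = int(ok.sum())
        if m == 0:
            continue
        dists.append(np.count_nonzero(mat[i, ok] != mat[j, ok]) / m)
    if not dists:
        raise ValueError("no pairwise-comparable columns")
    pi = float(np.mean(dists))
    if sample_size_correction:
        pi *= n / (n - 1)
    return pi


def pinpis_codon_matrix(cods: np.ndarray, tab: NG86Tables, locus_name: str = "",
                        pi: float = float("nan"), n_sites: float = float("nan")
                        ) -> DiversityResult:
    """piN/piS from a (n_rows, n_codons) codon-index matrix (64-space)."""
    n = cods.shape[0]
    dns, dss, sites = [], [], []
    for i, j in combinations(range(n), 2):
        sd, nd, s_sites, n_s = _codon_index_pair_stats(cods[i], cods[j], tab)
        if s_sites == 0 or n_s == 0:
            continue
        dss.append(jukes_cantor(sd / s_sites))
        dns.append(jukes_cantor(nd / n_s))
        sites.append(s_sites + n_s)
    if not dns or np.all(np.isnan(dns)) or np.all(np.isnan(dss)):
        raise ValueError(f"{locus_name}: all pairwise comparisons undefined")
    piN = float(np.nanmean(dns))
    piS = float(np.nanmean(dss))
    return DiversityResult(
        locus_name=locus_name, pi=pi, piN=piN, piS=piS, ratio=_ratio(piN, piS),
        n_sequences=n, n_sites_compared=float(np.mean(sites)) if sites else n_sites,
    )


def pinpis(alignment: LocusAlignment, code: GeneticCode,
           stop_policy: str = "exclude") -> DiversityResult:
    """Locus piN, piS and their ratio.

    piN (piS) is the mean over all sequence pairs of the NG86 dN (dS); the
    reported ratio is the ratio of these means, which stays defined when
    individual pairs have dS = 0. Ratio is 0 when piN = 0, and NA (NaN)
    when piN > 0 but piS = 0.
    """
    if alignment.n_rows < 2:
        raise ValueError("pinpis needs at least 2 sequences")
    tab = ng86_tables(code, stop_policy)
    res = pinpis_codon_matrix(alignment.codon_matrix(), tab,
                              locus_name=alignment.locus_name)
    res.pi = calculate_pi(alignment)
    return res


# ---------------------------------------------------------------------------
# per-site polymorphism classification
# ---------------------------------------------------------------------------

@dataclass
class SitePolymorphism:
    codon_index: int
    klass: str  # synonymous | nonsynonymous | both | invariant
    minority_individuals: tuple[str, ...] = field(default_factory=tuple)


def classify_sites(alignment: LocusAlignment, code: GeneticCode,
                   stop_policy: str = "exclude") -> list[SitePolymorphism]:
    """Label each codon column of a coding alignment by the kind of change
    segregating in it; drives the plot of piN>0 / piS>0 site clustering.

    Classification follows the NG86 pathway-averaged difference counts, so
    a column is (non)synonymous exactly when it contributes to piS (piN) —
    a codon pair whose endpoints encode the same amino acid but whose
    mutational pathways pass through a different one counts toward both.
    """
    tab = ng86_tables(code, stop_policy)
    cods = alignment.codon_matrix()
    inds = alignment.individuals
    out = []
    for k in range(cods.shape[1]):
        col = cods[:, k]
        carriers = [(ind, c) for ind, c in zip(inds, col) if c >= 0]
        distinct = sorted({c for _, c in carriers})
        if len(distinct) <= 1:
            out.append(SitePolymorphism(codon_index=k, klass="invariant"))
            continue
        syn = nonsyn = False
        for c1, c2 in combinations(distinct, 2):
            sd, nd = tab.diff_s[c1, c2], tab.diff_n[c1, c2]
            if np.isnan(sd):
                continue  # skipped pair (stop codon involvement)
            syn = syn or sd > 0
            nonsyn = nonsyn or nd > 0
        if not (syn or nonsyn):
            out.append(SitePolymorphism(codon_index=k, klass="invariant"))
            continue
        klass = "both" if (syn and nonsyn) else ("synonymous" if syn else "nonsynonymous")
        counts = {c: sum(1 for _, cc in carriers if cc == c) for c in distinct}
        major = max(distinct, key=lambda c: (counts[c], -c))
        minority = tuple(ind for ind, c in carriers if c != major)
        out.append(SitePolymorphism(codon_index=k, klass=klass,
                                    minority_individuals=minority))
    return out
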