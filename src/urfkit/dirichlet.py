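"""Bayesian coding-potential test via Dirichlet-multinomial Bayes factors.

The codon (3-mer) frequency spectrum of a query ORF is modelled as a
multinomial over the 62 sense codons. Two Dirichlet posteriors are formed
by conditioning a symmetric Dirichlet prior on the codon counts of known
protein-coding genes and on the in-frame 3-mer counts of known noncoding
(intergenic) sequence. The test statistic is the log Bayes factor

    log BF = log P(x | alpha_coding) - log P(x | alpha_noncoding)

where P(x | alpha) is the Dirichlet-multinomial (multivariate Polya)
marginal likelihood; log BF > 0 means the query's trinucleotide usage looks
more like coding sequence.

So that the classification cannot hinge on start/stop codons themselves,
sequences are preprocessed before counting: the leading start codon is
stripped, true ORFs lose their terminal stop, and noncoding sequences lose
every in-frame stop triplet — keeping the model strictly 62-dimensional.

Sensitivity and specificity are estimated by leave-one-out cross-validation:
each trial holds out one locus (all individuals' copies of it), conditions
the posteriors on one randomly chosen individual's copy of every remaining
locus, and scores one randomly chosen copy of the held-out locus (noncoding
queries get a uniformly random reading frame on the gene strand).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .alignment import LocusAlignment
from .codes import GeneticCode, codon_indices, seq_to_ints

logger = logging.getLogger("urfkit")


# ---------------------------------------------------------------------------
# preprocessing and counting
# ---------------------------------------------------------------------------

def preprocess_orf(seq: str, code: GeneticCode, status: str = "coding") -> str:
    """Strip start/stop information from an in-frame sequence.

    coding/test: remove the leading start codon (if present) and the
    terminal stop codon (if present). noncoding: remove the leading start
    codon (if present) and every in-frame stop triplet. A trailing partial
    triplet is dropped.
    """
    seq = seq.upper().replace("U", "T").replace("-", "")
    triplets = [seq[i : i + 3] for i in range(0, len(seq) - len(seq) % 3, 3)]
    if triplets and triplets[0] in code.start_codons:
        triplets = triplets[1:]
    if status in ("coding", "test"):
        if triplets and triplets[-1] in code.stop_codons:
            triplets = triplets[:-1]
    elif status == "noncoding":
        triplets = [t for t in triplets if t not in code.stop_codons]
    else:
        raise ValueError(f"unknown status {status!r}")
    out = "".join(triplets)
    if not out:
        raise ValueError("sequence empty after preprocessing")
    return out


@dataclass
class CodonCountVector:
    """Counts over the sense codons of a genetic code (stops excluded)."""

    locus_name: str
    individual: str
    frame: int
    counts: np.ndarray  # (n_sense,) nonnegative integers

    @property
    def n_codons(self) -> int:
        return int(self.counts.sum())


def count_codons(seq: str, frame: int, code: GeneticCode,
                 locus_name: str = "", individual: str = "") -> CodonCountVector:
    """Count non-overlapping in-frame triplets into the 62 sense-codon bins.

    Triplets containing N or a gap are skipped; stop triplets are not
    counted (they are not categories of the model); a trailing partial
    triplet is dropped.
    """
    if frame not in (0, 1, 2):
        raise ValueError("frame must be 0, 1 or 2")
    idx = codon_indices(seq_to_ints(seq), frame=frame)
    f2s = code.full_to_sense
    valid = idx[idx >= 0]
    sense = f2s[valid]
    counts = np.bincount(sense[sense >= 0], minlength=code.n_sense)
    return CodonCountVector(locus_name=locus_name, individual=individual,
                            frame=frame, counts=counts.astype(np.int64))


# ---------------------------------------------------------------------------
# posterior and marginal likelihood
# ---------------------------------------------------------------------------

@dataclass
class DirichletPosterior:
    label: str  # "coding" | "noncoding"
    alpha: np.ndarray
    conditioning_set: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.alpha = np.asarray(self.alpha, dtype=float)
        if (self.alpha <= 0).any():
            raise ValueError("all Dirichlet concentration parameters must be > 0")


def build_posterior(vectors: list[CodonCountVector], prior: np.ndarray,
                    label: str) -> DirichletPosterior:
    """alpha = prior + elementwise sum of the conditioning count vectors."""
    prior = np.asarray(prior, dtype=float)
    if (prior <= 0).any():
        raise ValueError("prior components must all be > 0")
    alpha = prior.copy()
    cset = []
    for v in vectors:
        alpha += v.counts
        cset.append((v.locus_name, v.individual))
    return DirichletPosterior(label=label, alpha=alpha, conditioning_set=cset)


def log_dirichlet_multinomial(x: np.ndarray, alpha: np.ndarray) -> float:
    """Log pmf of the Dirichlet-multinomial (multivariate Polya) distribution.

    Includes the multinomial coefficient, so probabilities over all count
    vectors with fixed total sum to 1. Stable via log-gamma for totals up
    to at least 1e5.
    """
    x = np.asarray(x, dtype=float)
    alpha = np.asarray(alpha, dtype=float)
    n = x.sum()
    a = alpha.sum()
    return float(
        gammaln(n + 1) - gammaln(x + 1).sum()
        + gammaln(a) - gammaln(a + n)
        + (gammaln(x + alpha) - gammaln(alpha)).sum()
    )


def log_marginal(x: CodonCountVector, post: DirichletPosterior) -> float:
    if x.n_codons < 1:
        raise ValueError("count vector must contain at least one codon")
    return log_dirichlet_multinomial(x.counts, post.alpha)


def log_bayes_factor(x: CodonCountVector, post_coding: DirichletPosterior,
                     post_noncoding: DirichletPosterior) -> float:
    """log marginal under coding minus under noncoding; > 0 is coding-like."""
    if post_coding.alpha.shape != post_noncoding.alpha.shape:
        raise ValueError("posteriors are over different category sets")
    return log_marginal(x, post_coding) - log_marginal(x, post_noncoding)


@dataclass
class BayesFactorResult:
    locus_name: str
    individual: str
    frame: int
    n_codons: int
    log_bf: float
    trial_index: int = -1
    seed: int | None = None


@dataclass
class LoocvSummary:
    power: float
    specificity: float
    n_trials: int
    n_coding_trials: int
    n_noncoding_trials: int
    prior: np.ndarray
    seed: int | None


# ---------------------------------------------------------------------------
# leave-one-out cross-validation
# ---------------------------------------------------------------------------

def _locus_count_arrays(loci: list[LocusAlignment], code: GeneticCode):
    """Precompute per-locus count matrices.

    coding locus  -> (n_individuals, K) counts of the preprocessed ORF
    noncoding     -> (n_individuals, 3, K): one spectrum per reading frame
    """
    coding, noncoding = [], []
    for loc in loci:
        if loc.status == "test":
            continue
        rows = loc.oriented_rows()
        inds = list(rows)
        if loc.status == "coding":
            mat = np.stack([
                count_codons(
                    preprocess_orf(rows[ind].replace("-", "")[loc.frame:], code, "coding"),
                    0, code
                ).counts
                for ind in inds
            ])
            coding.append((loc.locus_name, inds, mat))
        else:
            mat = np.stack([
                np.stack([
                    count_codons(
                        preprocess_orf(rows[ind].replace("-", "")[f:], code, "noncoding"),
                        0, code).counts
                    for f in range(3)
                ])
                for ind in inds
            ])
            noncoding.append((loc.locus_name, inds, mat))
    return coding, noncoding


def _log_dm_batch(X: np.ndarray, A: np.ndarray) -> np.ndarray:
    """Row-wise log Dirichlet-multinomial for matched (n, K) arrays."""
    n = X.sum(axis=1)
    a = A.sum(axis=1)
    return (
        gammaln(n + 1) - gammaln(X + 1).sum(axis=1)
        + gammaln(a) - gammaln(a + n)
        + (gammaln(X + A) - gammaln(A)).sum(axis=1)
    )


def loocv(
    loci: list[LocusAlignment],
    code: GeneticCode,
    prior: np.ndarray | None = None,
    n_trials: int = 100_001,
    seed: int | None = None,
    return_trials: bool = True,
) -> tuple[LoocvSummary, pd.DataFrame | None]:
    """Leave-one-out cross-validation of the coding/noncoding Bayes factor.

    Power is the fraction of coding-query trials with log BF > 0;
    specificity the fraction of noncoding-query trials with log BF < 0
    (log BF = 0 counts as a misclassification for both). Fully reproducible
    given ``seed``.
    """
    if seed is None:
        raise ValueError("loocv is stochastic; a seed is required")
    rng = np.random.default_rng(seed)
    if prior is None:
        prior = np.ones(code.n_sense)
    prior = np.asarray(prior, dtype=float)

    coding, noncoding = _locus_count_arrays(loci, code)
    if len(coding) < 2 or len(noncoding) < 2:
        raise ValueError("need >= 2 coding and >= 2 noncoding loci for LOOCV")

    # flat list of candidate (class, locus_pos, individual_pos) queries
    queries = [(0, li, ii) for li, (_, inds, _) in enumerate(coding) for ii in range(len(inds))]
    queries += [(1, li, ii) for li, (_, inds, _) in enumerate(noncoding) for ii in range(len(inds))]
    queries = np.array(queries)

    pick = rng.integers(0, len(queries), size=n_trials)
    q_class, q_locus, q_ind = queries[pick].T
    q_frame = np.where(q_class == 1, rng.integers(0, 3, size=n_trials), 0)

    # one random conditioning individual per locus per trial
    cod_choice = np.stack(
        [rng.integers(0, len(inds), size=n_trials) for _, inds, _ in coding], axis=1
    )
    non_choice = np.stack(
        [rng.integers(0, len(inds), size=n_trials) for _, inds, _ in noncoding], axis=1
    )
    non_frame = rng.integers(0, 3, size=(n_trials, len(noncoding)))

    K = code.n_sense
    cod_sum = np.zeros((n_trials, K))
    for li, (_, _, mat) in enumerate(coding):
        cod_sum += mat[cod_choice[:, li]]
    non_sum = np.zeros((n_trials, K))
    for li, (_, _, mat) in enumerate(noncoding):
        non_sum += mat[non_choice[:, li], non_frame[:, li]]

    # exclude the held-out locus (every individual of it) from its class
    X = np.zeros((n_trials, K))
    is_cod = q_class == 0
    for li, (_, _, mat) in enumerate(coding):
        m = is_cod & (q_locus == li)
        if m.any():
            cod_sum[m] -= mat[cod_choice[m, li]]
            X[m] = mat[q_ind[m]]
    for li, (_, _, mat) in enumerate(noncoding):
        m = (~is_cod) & (q_locus == li)
        if m.any():
            non_sum[m] -= mat[non_choice[m, li], non_frame[m, li]]
            X[m] = mat[q_ind[m], q_frame[m]]

    log_bf = (_log_dm_batch(X, prior + cod_sum)
              - _log_dm_batch(X, prior + non_sum))

    power = float((log_bf[is_cod] > 0).mean()) if is_cod.any() else float("nan")
    spec = float((log_bf[~is_cod] < 0).mean()) if (~is_cod).any() else float("nan")
    summary = LoocvSummary(
        power=power, specificity=spec, n_trials=n_trials,
        n_coding_trials=int(is_cod.sum()), n_noncoding_trials=int((~is_cod).sum()),
        prior=prior, seed=seed,
    )
    trials = None
    if return_trials:
        names = [(coding if c == 0 else noncoding)[l][0] for c, l in zip(q_class, q_locus)]
        individuals = [(coding if c == 0 else noncoding)[l][1][i]
                       for c, l, i in zip(q_class, q_locus, q_ind)]
        trials = pd.DataFrame({
            "trial": np.arange(n_trials),
            "locus": names,
            "individual": individuals,
            "status": np.where(is_cod, "coding", "noncoding"),
            "frame": q_frame,
            "n_codons": X.sum(axis=1).astype(int),
            "log_bf": log_bf,
        })
    return summary, trials


def classify_urf(
    urf_alignment: LocusAlignment,
    conditioning_loci: list[LocusAlignment],
    code: GeneticCode,
    prior: np.ndarray | None = None,
) -> list[BayesFactorResult]:
    """Score each individual's copy of a candidate ORF against posteriors
    conditioned on every known locus (all individuals' copies)."""
    if prior is None:
        prior = np.ones(code.n_sense)
    prior = np.asarray(prior, dtype=float)
    cod_vecs, non_vecs = [], []
    for loc in conditioning_loci:
        if loc.status == "test":
            continue
        rows = loc.oriented_rows()
        for ind, s in rows.items():
            if loc.status == "coding":
                cod_vecs.append(count_codons(
                    preprocess_orf(s[loc.frame:], code, "coding"), 0, code,
                    locus_name=loc.locus_name, individual=ind))
            else:
                for f in range(3):
                    non_vecs.append(count_codons(
                        preprocess_orf(s.replace("-", "")[f:], code, "noncoding"),
                        0, code, locus_name=loc.locus_name, individual=ind))
    post_c = build_posterior(cod_vecs, prior, "coding")
    post_n = build_posterior(non_vecs, prior, "noncoding")

    out = []
    rows = urf_alignment.oriented_rows()
    for ind, s in rows.items():
        x = count_codons(
            preprocess_orf(s.replace("-", "")[urf_alignment.frame:], code, "coding"),
            0, code, locus_name=urf_alignment.locus_name, individual=ind)
        out.append(BayesFactorResult(
            locus_name=urf_alignment.locus_name, individual=ind,
            frame=urf_alignment.frame, n_codons=x.n_codons,
            log_bf=log_bayes_factor(x, post_c, post_n)))
    return out
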