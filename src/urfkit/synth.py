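"""Synthetic mitogenome-like datasets with known truth.

The generator emulates the study system every statistical module is aimed
at: a small, AT-rich (~17% GC), circular genome carrying ~11 unidirectional
protein-coding genes separated by noncoding stretches of at least 50 bp,
sampled from three individuals of one population that differ by ~2% per
site. Lineages radiate from a single ancestor (a star phylogeny — the
natural model for few conspecific individuals), mutations arrive as a
Poisson process, and purifying selection is imposed by acceptance-rejection:
a proposed nonsynonymous change inside a coding locus is kept with
probability omega, synonymous and noncoding changes always. This gives
direct control of the expected piN/piS, so parameter-recovery and
calibration tests can compare estimates against a known truth. No indels
are introduced by default, so the individuals are trivially aligned.

Three presets cover the test surface:

* ``beroe-like`` — 13.3 kb, 11 genes under strong purifying selection plus
  two unlabeled test ORFs (one with omega = 0.3, one neutral), GC 0.173,
  ~2.2% divergence.
* ``neutral-null`` — every locus evolves with omega = 1; used for
  calibration of the permutation test.
* ``separable-toy`` — coding loci built from A/T-only codons and noncoding
  sequence from G/C-only bases, so the two classes have disjoint codon
  support and a correct classifier must approach perfect power/specificity.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .alignment import LocusAlignment
from .codes import ALL_CODONS, GeneticCode, ints_to_seq, load_genetic_code, seq_to_ints
from .io import AnnotationSet, Feature, SeqRecordMeta, write_fasta, write_gff3, write_tsv

PRESETS = ("beroe-like", "neutral-null", "separable-toy")

# locus lengths (nt, incl. start and stop codons) modelled on the gene-size
# range of a ctenophore mitogenome, shortest ~190 nt, longest ~1.8 kb
_BEROE_GENE_LENGTHS = (1569, 705, 783, 1137, 933, 957, 351, 1371, 189, 1767, 480)
_BEROE_TEST_LENGTHS = (1065, 669)


@dataclass
class SynthConfig:
    seed: int | None = None
    n_individuals: int = 3
    genome_length: int = 13300
    gc_target: float = 0.173
    n_coding_loci: int = 11
    coding_lengths: tuple[int, ...] | None = None  # nt incl. start+stop
    coding_codon_distribution: np.ndarray | None = None  # over sense codons
    noncoding_markov: np.ndarray | None = None  # 4x4 row-stochastic, ACGT
    per_site_mutation_rate: float = 0.011  # proposals per site per lineage
    omega: float = 0.1  # default nonsynonymous acceptance probability
    intergenic_min_len: int = 50

    def validate(self, code: GeneticCode) -> None:
        if not 0.0 <= self.omega <= 1.0:
            raise ValueError("omega must be in [0, 1]")
        if self.coding_codon_distribution is not None:
            p = np.asarray(self.coding_codon_distribution)
            if p.shape != (code.n_sense,) or abs(p.sum() - 1.0) > 1e-9 or (p < 0).any():
                raise ValueError("coding_codon_distribution must be a simplex "
                                 f"over the {code.n_sense} sense codons")
        if self.noncoding_markov is not None:
            m = np.asarray(self.noncoding_markov)
            if m.shape != (4, 4) or (np.abs(m.sum(axis=1) - 1.0) > 1e-9).any():
                raise ValueError("noncoding_markov must be a 4x4 row-stochastic matrix")


@dataclass
class TruthTable:
    """Ground truth of a generated dataset."""

    loci: pd.DataFrame  # locus, status, start, end, strand, omega
    mutation_counts: dict[tuple[str, str], int] = field(default_factory=dict)
    events: pd.DataFrame | None = None  # individual, pos, ref, alt, locus, synonymous

    def omega_of(self, locus: str) -> float:
        row = self.loci.loc[self.loci.locus == locus]
        return float(row.omega.iloc[0]) if len(row) else 1.0


def _base_probs(gc: float) -> np.ndarray:
    return np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])


# amino-acid weighting of the default coding distribution: mitochondrial
# protein-coding genes (mostly membrane proteins) are rich in hydrophobic
# residues, which is what makes their codon spectrum distinguishable from
# the trinucleotide spectrum of intergenic sequence of the same base
# composition.
_AA_WEIGHTS = {"F": 3.0, "L": 3.0, "I": 3.0, "V": 2.0, "M": 2.0,
               "S": 1.8, "T": 1.3, "A": 1.3, "G": 1.3, "Y": 1.5, "W": 1.5}


def default_coding_distribution(code: GeneticCode, gc: float) -> np.ndarray:
    """Sense-codon simplex at overall base composition *gc*, tilted toward
    hydrophobic amino acids so coding and noncoding spectra differ."""
    b = _base_probs(gc)
    p = np.array([
        b[ALL_CODONS.index(c) // 16] * b[(ALL_CODONS.index(c) // 4) % 4]
        * b[ALL_CODONS.index(c) % 4]
        * _AA_WEIGHTS.get(code.codon_to_aa[c], 1.0)
        for c in code.sense_codons
    ])
    return p / p.sum()


def _sample_noncoding(length: int, markov: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    stationary = markov.mean(axis=0) / markov.mean(axis=0).sum()
    out = np.empty(length, dtype=np.int8)
    out[0] = rng.choice(4, p=stationary)
    for i in range(1, length):
        out[i] = rng.choice(4, p=markov[out[i - 1]])
    return out


def _default_lengths(cfg: SynthConfig, rng: np.random.Generator) -> tuple[int, ...]:
    if cfg.coding_lengths is not None:
        return tuple(cfg.coding_lengths)
    if cfg.n_coding_loci == 0:
        return ()
    # aim at ~75% coding density with variable gene sizes; relative sizes
    # are drawn and then scaled so the loci always fit the genome
    budget_aa = int(0.75 * cfg.genome_length) // 3 - 2 * cfg.n_coding_loci
    weights = rng.uniform(0.5, 2.0, size=cfg.n_coding_loci)
    n_aa = np.maximum(20, (budget_aa * weights / weights.sum()).astype(int))
    return tuple(int(3 * (m + 2)) for m in n_aa)


def gen_ancestor(
    config: SynthConfig,
    code: GeneticCode | None = None,
    rng: np.random.Generator | None = None,
    per_locus_omega: dict[str, float] | None = None,
    test_lengths: tuple[int, ...] = (),
) -> tuple[SeqRecordMeta, AnnotationSet, TruthTable]:
    """Generate the ancestral circular genome, its annotation and truth.

    Coding loci (and any ``test_lengths`` extra unlabeled ORFs) are built as
    start codon + codons drawn i.i.d. from the coding codon distribution +
    stop codon, so they translate without internal stops by construction.
    Intergenic stretches come from the noncoding Markov chain and are all at
    least ``intergenic_min_len`` long.
    """
    code = code or load_genetic_code(4)
    config.validate(code)
    rng = rng or np.random.default_rng(config.seed)

    lengths = list(_default_lengths(config, rng))
    statuses = ["coding"] * len(lengths)
    names = [f"gene{i+1}" for i in range(len(lengths))]
    for i, tl in enumerate(test_lengths):
        lengths.append(int(tl))
        statuses.append("test")
        names.append(f"urf{i+1}")
    if any(l % 3 or l < 9 for l in lengths):
        raise ValueError("locus lengths must be multiples of 3 and >= 9")

    n_loci = len(lengths)
    total_coding = sum(lengths)
    n_gaps = max(n_loci, 1)
    spare = config.genome_length - total_coding - n_gaps * config.intergenic_min_len
    if spare < 0:
        raise ValueError(
            f"loci ({total_coding} nt) plus minimal intergenic spacers do not "
            f"fit in genome_length={config.genome_length}"
        )
    extra = rng.multinomial(spare, np.full(n_gaps, 1 / n_gaps))
    gap_lengths = config.intergenic_min_len + extra

    p_codon = (np.asarray(config.coding_codon_distribution)
               if config.coding_codon_distribution is not None
               else default_coding_distribution(code, config.gc_target))
    markov = (np.asarray(config.noncoding_markov)
              if config.noncoding_markov is not None
              else np.tile(_base_probs(config.gc_target), (4, 1)))

    sense_ints = np.stack([seq_to_ints(c) for c in code.sense_codons])
    start_ints, stop_ints = seq_to_ints("ATG"), seq_to_ints("TAA")

    chunks, feats, rows = [], [], []
    pos = 0
    for i in range(n_loci):
        gl = int(gap_lengths[i])
        chunks.append(_sample_noncoding(gl, markov, rng))
        feats.append(Feature(name=f"igs{i+1}", type="intergenic", start=pos, end=pos + gl))
        rows.append((f"igs{i+1}", "noncoding", pos, pos + gl, "+", 1.0))
        pos += gl
        m = lengths[i] // 3 - 2
        body = sense_ints[rng.choice(code.n_sense, size=m, p=p_codon)].ravel()
        chunks.append(np.concatenate([start_ints, body, stop_ints]).astype(np.int8))
        ftype = "gene" if statuses[i] == "coding" else "URF"
        feats.append(Feature(name=names[i], type=ftype, start=pos, end=pos + lengths[i]))
        omega = (per_locus_omega or {}).get(names[i], config.omega)
        rows.append((names[i], statuses[i], pos, pos + lengths[i], "+", omega))
        pos += lengths[i]
    if pos < config.genome_length:  # trailing spacer closes the circle
        gl = config.genome_length - pos
        chunks.append(_sample_noncoding(gl, markov, rng))
        feats.append(Feature(name=f"igs{n_loci+1}", type="intergenic", start=pos, end=pos + gl))
        rows.append((f"igs{n_loci+1}", "noncoding", pos, pos + gl, "+", 1.0))
        pos += gl

    genome = np.concatenate(chunks) if chunks else _sample_noncoding(
        config.genome_length, markov, rng)
    record = SeqRecordMeta(id="ancestor", sequence=ints_to_seq(genome),
                           individual="ancestor", circular=True)
    annotations = AnnotationSet(seqid="ancestor", features=feats, seq_length=len(genome))
    truth = TruthTable(loci=pd.DataFrame(
        rows, columns=["locus", "status", "start", "end", "strand", "omega"]))
    return record, annotations, truth


def evolve_population(
    ancestor: SeqRecordMeta,
    truth: TruthTable,
    config: SynthConfig,
    code: GeneticCode | None = None,
    rng: np.random.Generator | None = None,
    individual_names: list[str] | None = None,
) -> tuple[dict[str, SeqRecordMeta], TruthTable]:
    """Evolve ``n_individuals`` lineages independently from the ancestor.

    Each lineage draws Poisson(rate x length) mutation proposals at uniform
    positions; proposals that change an amino acid inside a coding or test
    locus are accepted with that locus' omega. Accepted events are recorded
    in the returned TruthTable.
    """
    code = code or load_genetic_code(4)
    rng = rng or np.random.default_rng(config.seed)
    anc = seq_to_ints(ancestor.sequence)
    L = anc.size
    names = individual_names or [f"ind{i+1}" for i in range(config.n_individuals)]

    # per-position locus lookup for coding/test loci
    locus_id = np.full(L, -1, dtype=np.int64)
    locus_start = np.zeros(L, dtype=np.int64)
    sel = truth.loci[truth.loci.status.isin(["coding", "test"])].reset_index()
    omegas = sel.omega.to_numpy()
    for k, row in sel.iterrows():
        locus_id[row.start:row.end] = k
        locus_start[row.start:row.end] = row.start
    locus_names_all = truth.loci.locus.to_numpy()
    locus_of_pos = np.full(L, "", dtype=object)
    for _, row in truth.loci.iterrows():
        locus_of_pos[row.start:row.end] = row.locus

    aa = code.aa_codes
    genomes: dict[str, SeqRecordMeta] = {}
    events = []
    counts: dict[tuple[str, str], int] = {
        (loc, ind): 0 for loc in locus_names_all for ind in names
    }
    for ind in names:
        g = anc.copy()
        n_prop = rng.poisson(config.per_site_mutation_rate * L)
        positions = rng.integers(0, L, size=n_prop)
        shifts = rng.integers(1, 4, size=n_prop)
        for pos, shift in zip(positions, shifts):
            old = g[pos]
            new = (old + shift) % 4
            lid = locus_id[pos]
            synonymous = True
            if lid >= 0:
                cs = locus_start[pos] + 3 * ((pos - locus_start[pos]) // 3)
                old_codon = g[cs] * 16 + g[cs + 1] * 4 + g[cs + 2]
                codon = [g[cs], g[cs + 1], g[cs + 2]]
                codon[pos - cs] = new
                new_codon = codon[0] * 16 + codon[1] * 4 + codon[2]
                synonymous = aa[old_codon] == aa[new_codon]
                if not synonymous and rng.random() >= omegas[lid]:
                    continue  # purged by purifying selection
            g[pos] = new
            loc = locus_of_pos[pos]
            if loc:
                counts[(loc, ind)] += 1
            events.append((ind, int(pos), "ACGT"[old], "ACGT"[new], loc, bool(synonymous)))
        genomes[ind] = SeqRecordMeta(id=ind, sequence=ints_to_seq(g),
                                     individual=ind, circular=ancestor.circular)
    truth = replace(
        truth,
        mutation_counts=counts,
        events=pd.DataFrame(events, columns=["individual", "pos", "ref", "alt",
                                             "locus", "synonymous"]),
    )
    return genomes, truth


def extract_locus_alignments(
    genomes: dict[str, SeqRecordMeta], truth: TruthTable
) -> list[LocusAlignment]:
    """Slice per-locus alignments out of the (indel-free) population."""
    out = []
    for _, row in truth.loci.iterrows():
        rows = {ind: rec.sequence[row.start:row.end] for ind, rec in genomes.items()}
        out.append(LocusAlignment(locus_name=row.locus, rows=rows, status=row.status,
                                  frame=0, strand=row.strand))
    return out


@dataclass
class SynthDataset:
    preset: str
    config: SynthConfig
    code: GeneticCode
    ancestor: SeqRecordMeta
    annotations: AnnotationSet
    truth: TruthTable
    genomes: dict[str, SeqRecordMeta]
    loci: list[LocusAlignment]

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(list(self.genomes.values()), outdir / "genomes.fa")
        write_fasta([self.ancestor], outdir / "ancestor.fa")
        write_gff3(self.annotations, outdir / "annotations.gff3")
        labels = self.truth.loci[["locus", "status", "strand", "start", "end"]].copy()
        labels["frame"] = 0
        write_tsv(labels, outdir / "labels.tsv")
        tt = self.truth.loci.copy()
        for ind in self.genomes:
            tt[f"n_mut_{ind}"] = [
                self.truth.mutation_counts.get((loc, ind), 0) for loc in tt.locus
            ]
        write_tsv(tt, outdir / "truth.tsv")
        loci_dir = outdir / "loci"
        loci_dir.mkdir(exist_ok=True)
        for loc in self.loci:
            write_fasta(
                [SeqRecordMeta(id=ind, sequence=s, individual=ind)
                 for ind, s in loc.rows.items()],
                loci_dir / f"{loc.locus_name}.fa",
            )


def _preset_config(preset: str, seed: int | None) -> tuple[SynthConfig, dict, tuple]:
    if preset == "beroe-like":
        cfg = SynthConfig(seed=seed, coding_lengths=_BEROE_GENE_LENGTHS, omega=0.05)
        per_locus = {"urf1": 0.3, "urf2": 1.0}
        return cfg, per_locus, _BEROE_TEST_LENGTHS
    if preset == "neutral-null":
        cfg = SynthConfig(seed=seed, genome_length=6000, n_coding_loci=5,
                          coding_lengths=(900, 903, 999, 1200, 906), omega=1.0)
        return cfg, {}, ()
    if preset == "separable-toy":
        at_codons = ("AAA", "AAT", "ATA", "ATT", "TAT", "TTA", "TTT")
        code = load_genetic_code(4)
        p = np.zeros(code.n_sense)
        for c in at_codons:
            p[code.sense_codons.index(c)] = 1.0 / len(at_codons)
        markov = np.tile(np.array([0.0, 0.5, 0.5, 0.0]), (4, 1))  # G/C only
        cfg = SynthConfig(seed=seed, genome_length=4000, n_coding_loci=4,
                          coding_lengths=(420, 510, 600, 720),
                          coding_codon_distribution=p, noncoding_markov=markov,
                          per_site_mutation_rate=0.005, omega=0.5,
                          gc_target=0.173)
        return cfg, {}, ()
    raise ValueError(f"unknown preset {preset!r}; available presets: {', '.join(PRESETS)}")


def make_fixture(preset_name: str, seed: int | None = None,
                 outdir: str | Path | None = None) -> SynthDataset:
    """Build a preset dataset (optionally writing FASTA/GFF3/TSV to disk)."""
    cfg, per_locus_omega, test_lengths = _preset_config(preset_name, seed)
    code = load_genetic_code(4)
    rng = np.random.default_rng(seed)
    ancestor, annotations, truth = gen_ancestor(
        cfg, code, rng, per_locus_omega=per_locus_omega, test_lengths=test_lengths)
    genomes, truth = evolve_population(ancestor, truth, cfg, code, rng)
    loci = extract_locus_alignments(genomes, truth)
    ds = SynthDataset(preset=preset_name, config=cfg, code=code, ancestor=ancestor,
                      annotations=annotations, truth=truth, genomes=genomes, loci=loci)
    if outdir is not None:
        ds.write(outdir)
    return ds
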