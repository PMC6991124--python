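"""Find ORFs conserved across all individuals of a small genome.

Generates a three-individual mitogenome-like population, then reports every
ORF (>= 600 nt) whose span is an intact reading frame — start codon present,
no internal stops — in all three individuals. This is the rule used to
delimit candidate unidentified reading frames (URFs).
"""

from urfkit import conserved_orfs, load_genetic_code, make_fixture, translate

code = load_genetic_code("mold-protozoan-coelenterate")  # NCBI table 4
ds = make_fixture("beroe-like", seed=11)
rows = {name: rec.sequence for name, rec in ds.genomes.items()}

orfs = conserved_orfs(rows, code, min_len_nt=600)
print(f"{len(orfs)} conserved ORFs >= 600 nt in {len(rows)} individuals")
for o in orfs:
    aa = o.length_aa
    print(f"  {o.start:>6}-{o.end:<6} {o.strand}  {o.length_nt:>5} nt  ~{aa} aa")

# Which of these are the planted, unannotated test ORFs?
truth = ds.truth.loci
for _, row in truth[truth.status == "test"].iterrows():
    hit = any(o.end == row.end for o in orfs)
    print(f"planted {row.locus} ({row.end - row.start} nt, omega={row.omega}): "
          f"{'recovered' if hit else 'disrupted by mutation in some individual'}")
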