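"""Nucleotide diversity, piN/piS, and per-site polymorphism classes.

For each coding locus of a synthetic three-individual population, computes
Nei-Li pi and the NG86 piN/piS ratio. A ratio well below 1 indicates
purifying selection (nonsynonymous variants are being removed); the
generator's true omega is printed alongside for comparison.
"""

from urfkit import classify_sites, load_genetic_code, make_fixture, pinpis

code = load_genetic_code(4)
ds = make_fixture("beroe-like", seed=11)

print(f"{'locus':<8}{'pi':>9}{'piN':>9}{'piS':>9}{'piN/piS':>9}{'true omega':>12}")
for loc in ds.loci:
    if loc.status == "noncoding":
        continue
    r = pinpis(loc, code)
    omega = ds.truth.omega_of(loc.locus_name)
    print(f"{loc.locus_name:<8}{r.pi:>9.4f}{r.piN:>9.4f}{r.piS:>9.4f}"
          f"{r.ratio:>9.4f}{omega:>12.2f}")

# where do the polymorphic codons fall along one gene?
loc = ds.loci[1]
sites = classify_sites(loc, code)
poly = [s for s in sites if s.klass != "invariant"]
print(f"\n{loc.locus_name}: {len(poly)} polymorphic codons of {len(sites)}")
for s in poly:
    print(f"  codon {s.codon_index:>4}: {s.klass:<14} minority={','.join(s.minority_individuals)}")
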