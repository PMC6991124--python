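"""Is a low piN/piS actually evidence of selection? The permutation test.

The nucleotide diversity permutation simulation (NDPS) keeps the inferred
ancestor and each lineage's mutation count fixed, scatters the mutations
uniformly (no selection), and asks how often neutral chance alone produces
a piN/piS as low as observed. Small Monte-Carlo p = purifying selection.

The gene under strong purifying selection (omega = 0.05) gets a tiny p;
the neutrally evolving test ORF does not. The omega = 0.3 ORF sits in
between — with only a handful of segregating mutations the test has
limited power there, exactly the regime where a Monte-Carlo p-value is
more trustworthy than the raw ratio.
"""

from urfkit import load_genetic_code, make_fixture, ndps_run

code = load_genetic_code(4)
ds = make_fixture("beroe-like", seed=11)

for name in ("gene1", "urf1", "urf2"):
    loc = [l for l in ds.loci if l.locus_name == name][0]
    res = ndps_run(loc, code, n_sims=1000, seed=42)
    omega = ds.truth.omega_of(name)
    print(f"{name:<6} true omega={omega:<5} observed piN/piS={res.observed_ratio:.4f}  "
          f"MC p={res.mc_p:.4f}  ({res.n_valid} valid simulations)")
print("\nSmall p: neutral mutation rarely yields a ratio this low -> selection.")
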