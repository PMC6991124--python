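"""Codon-usage Bayes factors: does an ORF look like a coding gene?

Conditions Dirichlet posteriors on the codon spectra of known coding genes
and the in-frame 3-mer spectra of intergenic sequence, then (1) estimates
the classifier's power/specificity by leave-one-out cross-validation and
(2) scores the two unannotated test ORFs. log BF > 0 means the ORF's
trinucleotide usage is more coding-like.
"""

from urfkit import classify_urf, load_genetic_code, loocv, make_fixture

code = load_genetic_code(4)
ds = make_fixture("beroe-like", seed=11)

summary, trials = loocv(ds.loci, code, n_trials=20_001, seed=7)
print(f"LOOCV over {summary.n_trials} trials: "
      f"power={summary.power:.3f} specificity={summary.specificity:.3f}")

med = trials.groupby(["locus", "status"], observed=True).log_bf.median()
print("\nmedian log BF by held-out locus (positive = coding-like):")
for (locus, status), m in med.sort_values().items():
    print(f"  {locus:<8}{status:<11}{m:>9.2f}")

print("\nunannotated test ORFs vs posteriors on all known loci:")
for loc in ds.loci:
    if loc.status == "test":
        for r in classify_urf(loc, ds.loci, code):
            print(f"  {r.locus_name}/{r.individual}: log BF = {r.log_bf:.2f}")
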