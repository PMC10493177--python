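"""Generate a synthetic genotype cohort from a toy reference panel.

Builds a 200-haplotype fixture panel with block LD structure, synthesizes
100 diploid genotypes by mosaic copying, and writes them as PLINK1
bed/bim/fam.
"""

import mosaicsim as ms

panel, gmap, ages = ms.generate_panel(ms.FixtureSpec(n_hap=200, n_snp=2000, seed=1))
print(f"reference panel: {panel.n_haplotypes} haplotypes x {panel.n_variants} SNPs")

params = ms.SimParams(n_samples=100, rho=2.185, ne=500.0, seed=42)
cohort = ms.synthesize_cohort(panel, gmap, ages, params, out_path="cohort",
                              format="plink-bed")
print(f"synthetic cohort: {cohort.n_samples} samples -> cohort.bed/.bim/.fam")
print(f"mean dosage {cohort.dosages.mean():.3f} (alt-allele count per genotype; "
      "2x the mean alt frequency after the mutation-age filter)")
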