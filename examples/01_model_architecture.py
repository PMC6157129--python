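"""The default causal architecture: who affects the drug-response slope, how.

Builds the compiled-in model spec and prints the variance budget of the
standardized slope: each major SNP's heritability (its share of slope
variance when its gating CpG is unmethylated), the polygenic background,
and the residual.
"""
import genomethate as g

spec = g.default_spec()

print(f"SNP effects: {len(spec.snps)} "
      f"({len(spec.major_snps)} major + {len(spec.background_snps)} background)")
print(f"CpG sites:   {len(spec.causal_cpgs)} causal, "
      f"{len(spec.red_herring_cpgs)} red-herring (noise SD 0.4)")
print()
print("major SNP      hg2     coeff=sqrt(hg2)  gating CpG")
for snp in spec.major_snps:
    cpg = spec.causal_cpg_for_snp(snp.marker_name)
    print(f"{snp.marker_name:<12s} {snp.hg2:>6.3f}  {g.effect_coefficient(snp):>12.4f}   {cpg.cpg_name}")
bg = spec.background_snps[0]
print(f"({len(spec.background_snps)} background SNPs like {bg.marker_name}: "
      f"hg2 = {bg.hg2} each)")
print()
print(f"sum of hg2        = {spec.total_hg2:.3f}")
print(f"residual scale    = sqrt(1 - {spec.total_hg2:.3f}) = {spec.residual_scale:.6f}")
print(f"slope/baseline correlation constant = {spec.corr_baseline}")
# The variance budget sums to 1: a fully unmethylated cohort yields a
# standardized slope with unit variance.
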