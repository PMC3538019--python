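"""In-silico forced-RFLP: design, digestion patterns, population genotyping.

A forced-RFLP assay genotypes a SNP that does not touch any natural
restriction site: the forward primer ends immediately 5' of the SNP and
carries one substituted base near its 3' end, so that the amplified product
— but not the genomic template — contains a complete recognition site for
exactly one allele.
"""
from pyroaei import (
    PopulationSpec,
    SnpSpec,
    digest,
    generate_rflp_template,
    genotype_population,
    get_enzyme,
    select_heterozygotes,
    simulate_genotypes,
)
import pandas as pd

syn = generate_rflp_template(("G", "A"), get_enzyme("PvuII"), force_site=True, seed=1)
assay = syn.assay
print(f"enzyme            : PvuII ({assay.enzyme.recognition})")
print(f"forward primer    : {assay.primers.forward}  forced={assay.primers.forward_forced}")
print(f"template digest A : {digest(syn.templates['A'], assay.enzyme).fragment_lengths}")
print(f"template digest B : {digest(syn.templates['B'], assay.enzyme).fragment_lengths}")
print(f"amplicon digest A : {assay.expected_a.fragment_lengths}")
print(f"amplicon digest B : {assay.expected_b.fragment_lengths}")
print()
print(
    "The undigested templates give a single fragment for BOTH alleles — the\n"
    f"diagnostic site exists only after primer incorporation, and only allele\n"
    f"{syn.cut_allele}'s amplicon is cut."
)

# genotype a Hardy-Weinberg population and apply the heterozygosity filter
spec = PopulationSpec(n_animals=40, snps=(SnpSpec("SYN", "G", "A", 0.3),))
truth = simulate_genotypes(spec, seed=11)["SYN"]
calls = genotype_population(assay, syn.templates, truth)
recovered = pd.Series({c.animal: c.call for c in calls})
print(f"\ngenotype recovery : {(recovered == truth).mean():.0%} of 40 animals")
sel = select_heterozygotes(recovered.to_frame("SYN"), min_het_fraction=0.125)["SYN"]
print(
    f"heterozygotes     : {sel.n_het}/40 (need >= {sel.min_required} at 12.5 %) -> "
    f"{'enter' if sel.passed else 'excluded from'} the expression analysis"
)
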