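"""Estimate haplotype frequencies and Lewontin's D' by EM.

Unphased two-locus genotypes leave only the double heterozygotes
phase-ambiguous; EM splits them cis/trans by current frequency products and
converges in a handful of iterations.  D' = |D|/Dmax summarises LD.
"""

from amplisnp import em_haplotype_freqs, ld_stats, simulate_genotypes
from amplisnp.simulate import DEFAULT_HAP_FREQS

g = simulate_genotypes(DEFAULT_HAP_FREQS, 2000, seed=3)
est = em_haplotype_freqs(g[:, 0], g[:, 1])
ld = ld_stats(est)

for label, f_hat, f_true in zip(
    ("TA", "TG", "CA", "CG"), est.freqs.as_array(), DEFAULT_HAP_FREQS.as_array()
):
    print(f"freq[{label}] = {f_hat:.4f}   (truth {f_true:.4f})")
print(f"EM converged in {est.n_iter} iterations, loglik {est.loglik:.2f}")
print(f"D = {ld.D:.4f}  Dmax = {ld.Dmax:.4f}  D' = {ld.Dprime:.3f}")
print("D' near 0.91 reflects the strong LD built into the generator.")
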