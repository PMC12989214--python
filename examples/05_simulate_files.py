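"""Write a synthetic GWAS triplet to disk and read it back through the I/O layer.

Produces exposure/mediator/outcome summary-statistics TSVs, the generating
LD matrix, and truth.json under scratch/triplet_demo/, then re-reads one file
with a column map to show the dialect adapter.
"""

from mrmediate import SimulationTruth, read_sumstats, write_triplet

truth = SimulationTruth(seed=5, n_snps=10, n_mediator_snps=10,
                        n_exposure_cohort=5_000, n_mediator_cohort=5_000,
                        n_outcome_cohort=5_000, ld_block_size=5, ld_rho=0.6)
write_triplet(truth, "scratch/triplet_demo")
print("wrote scratch/triplet_demo/{exposure,mediator,outcome}_sumstats.tsv, "
      "ld_matrix.tsv, truth.json")

records = read_sumstats("scratch/triplet_demo/exposure_sumstats.tsv")
print(f"\nexposure table: {len(records)} SNPs; first record:")
r = records[0]
print(f"  {r.snp_id} {r.effect_allele}/{r.other_allele} eaf={r.eaf:.3f} "
      f"beta={r.beta:+.4f} se={r.se:.4f} p={r.pval:.2e} n={r.n}")
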