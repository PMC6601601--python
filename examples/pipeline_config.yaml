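# Example pipeline configuration for `amplisnp run-all --config <this file>`.
# Every key is optional; omitted keys fall back to the defaults shown in
# docs/methods.md.

out_dir: scratch/config_run      # all stage outputs land here
seed: 7                          # drives every source of randomness

# --- input mode -------------------------------------------------------------
# Fully synthetic run: generate cohort + reads, then analyse them.
simulate: true
simulate_reads: true             # false: analyse the simulated cohort's
                                 # genotype columns directly (no FASTQ stage)

# For real data instead, set simulate: false and provide:
# cohort_path: my_cohort.tsv     # sample_id, status, age, bmi, traits ...
# fastq_dir: fastq/              # one <sample_id>.fastq[.gz] per sample

# --- synthetic cohort -------------------------------------------------------
cohort_config:
  n_case: 60
  n_control: 60
  # beta_geno: 0.8416            # log-OR of the genotype effect (default log 2.32)
  # geno_coding: overdominant    # dominant | recessive | overdominant | additive

# --- read simulator ---------------------------------------------------------
read_sim:
  depth: 400                     # reads per sample (study-scale target: 20000)
  per_base_error: 0.005
  read_length: 150

# --- genotype caller --------------------------------------------------------
call_params:
  min_mean_q: 20.0               # strict: mean Phred must exceed this
  min_len: 100
  min_depth: 50                  # informative reads below this -> no_call
  het_low: 0.2                   # alt fraction below -> hom_ref
  het_high: 0.8                  # alt fraction above -> hom_alt

# --- association ------------------------------------------------------------
covariates: [age, bmi]
alpha: 0.05
bonferroni_k: 2                  # significance threshold alpha / k

# A custom amplicon design may be given inline (same schema as
# `amplisnp.save_design` writes): amplicon_seq, adapter, snps[].
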