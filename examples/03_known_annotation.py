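"""Annotate collapsed reads against a reference mature set.

Homology annotation (<= 2 substitutions over >= 18 nt), the 3-library /
5-read support filter, family assignment and TPM, printed as the known-
miRNA catalogue table.
"""

from mirslice import annotate, pipeline, simulate

cfg = simulate.SimulationConfig(
    n_transcripts=40, n_planted_mirnas=8, depth_per_library=5_000,
    degradome_depth=0, n_planted_targets=0, mean_mirna_reads_per_library=60,
    seed=7,
)
study = simulate.simulate_study(cfg)
result = pipeline.run_pipeline(study)

print(f"{'name':<18} {'family':<9} {'mm':>2} {'counts':<22} {'TPM (max)':>9}")
for a in result.annotations:
    counts = ",".join(map(str, a.counts))
    print(f"{a.ref_name:<18} {a.family:<9} {a.mismatches:>2} {counts:<22} {max(a.tpm):>9.0f}")

scores = pipeline.score_known_recovery(result, study.truth)
print(f"\nrecovered {scores['n_recovered']}/{scores['n_planted_known']} planted "
      f"known miRNAs; precision {scores['precision']:.2f}")
# Every planted mature expressed above the support threshold should be
# recovered with its correct family and no false annotations.
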