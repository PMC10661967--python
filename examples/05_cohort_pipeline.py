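"""Reduced synthetic study end-to-end: simulate, analyse, compare groups.

Three groups (control; power attenuated; power and coupling attenuated) are
simulated at reduced scale (4 subjects x 2 channels x 60 s instead of
6 x 8 x 300 s) so the example runs in seconds, then band powers and MI are
compared across groups.  The expected pattern: band powers reduced in both
attenuated groups, MI reduced only where coupling depth was attenuated.
"""

from lfpac import PipelineConfig, SyntheticCohortSpec, run_pipeline

cohort = SyntheticCohortSpec(n_subjects_per_group=4, n_channels=2,
                             duration_s=60.0, seed=5)
report = run_pipeline(PipelineConfig(cohort=cohort, outdir="scratch/example_run"))

c = report.comparisons
inferential = c[c["test"].isin(["anova", "tamhane_t2", "wilcoxon_rank_sum"])]
print("inferential tests (alpha = 0.05):")
for _, row in inferential.iterrows():
    pair = (f"{row['group_a']} vs {row['group_b']}" if row["group_a"]
            else "omnibus")
    flag = "*" if row["significant"] else " "
    print(f" {flag} {row['metric']:<10s} {row['band']:<17s} "
          f"{row['test']:<17s} {pair:<24s} p={row['p_adj']:.4f}")
print(f"\ntables written to {report.outdir}; at the full study scale "
      "(6 subjects x 8 channels x 300 s) every band power is reduced in both "
      "attenuated groups and MI only in the coupling-attenuated one.")
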