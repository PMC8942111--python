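"""Cohort analysis: does breathing SNR track the self-reported health scale?

Simulates a small cohort (healthy subjects skewed toward high health scores,
COPD subjects near 5.5/10), runs the session pipeline on every subject, and
tests for a positive rank correlation between health scale and mean SNR
with a one-sided permutation test.
"""

import numpy as np

import breathsnr as bs

outs, metadata = bs.simulate_cohort(n_healthy=16, n_copd=2, seed=3,
                                    program=bs.BreathProgram.short())
rows = []
for sim in outs:
    results, _ = bs.session_snr(sim.recording)
    rows.append({"subject_id": sim.subject.subject_id,
                 "group": sim.subject.group,
                 "health_scale": sim.subject.health_scale,
                 "mean_snr_db": bs.aggregate_subject(list(results.values()))})
table = bs.build_table(rows)

corr = bs.correlation_test(table, n_permutations=999, seed=0)
norm = bs.group_normalize(table)
print(f"n = {len(table)} subjects "
      f"({(metadata['group'] == 'copd').sum()} COPD)")
print(f"Spearman rho = {corr.rho:.3f}, one-sided permutation p = "
      f"{corr.p_value:.4f}")
print("\nnormalized group-mean SNR per occupied health scale:")
for r in norm.itertuples():
    print(f"  scale {r.health_scale:2d}: {r.normalized:.2f} "
          f"({r.mean_snr_db:6.2f} dB)")

print("\nA positive rho with small p says subjects reporting better health")
print("breathe with systematically higher acoustic SNR.")
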