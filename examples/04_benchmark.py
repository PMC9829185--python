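"""Reduced-scale simulation study: discovery rules and replication curves.

Simulates ascertained locus pools under H0/H1/H2, selects candidates by the
conditional-threshold rule (focal-SNP p < 0.01), the likelihood-ratio
colocalization test (p < 0.01), a calibrated posterior-product threshold,
and the consensus intersection, then projects replication across validation
cohort sizes.
"""

from pleioscan import BenchConfig, SimParams, run_benchmark

cfg = BenchConfig(
    T=300,
    replicates=10,
    n_panels=8,
    m=200,
    pool_h0=600,
    pool_h1=250,
    pool_h2_per_bin=120,
    sim=SimParams(n_null=600),
)
res = run_benchmark(cfg, seed=1)

print("P(selected | true class) per rule:")
print(res["rates"].round(4).to_string())
print("\nExpected % of selected loci that are H2 (30% H0, H1:H2 = 1:19):")
for method, pct in res["contamination"].items():
    print(f"  {method:>15}: {pct:5.1f}%")
print("\nReplication curves (mean over scenario draws):")
print(res["curves"].round(2).to_string(index=False))
print(f"\nwall time: {res['wall_time_s']:.0f}s")
print("The consensus keeps fewer loci than either rule alone but its")
print("replicated fraction is dominated by shared-variant (H1) loci.")
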