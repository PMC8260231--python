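"""Androgen-sensitive DMP screen and TF-binding enrichment at the top hits.

Finds probes whose methylation-age slope differs between intact and
castrated males, checks their chromosomal spread, and asks whether any
transcription factor's peaks cover the top 50 more often than random
same-size probe sets (1000 bootstrap replicates).
"""

import ovisclock as oc

dataset, tf_table, truth = oc.simulate_dataset(oc.SimConfig(
    n_samples=300, n_probes=2000, n_clock_probes=0, n_asdmp_probes=60,
    seed=5))

results = oc.asdmp_screen(dataset,
                          "sex == 'male' and not castrated",
                          "sex == 'male' and castrated")
planted = set(truth.index[truth["role"] == "asdmp"])
sig = results[results["p"] < 1e-4]
print(f"asDMPs at p < 1e-4: {len(sig)} "
      f"({len(set(sig['probe_id']) & planted)} planted)")

top50 = oc.rank_and_select(results, k=50)
n_hypo = int((results.loc[top50, "direction"] < 0).sum())
print(f"top 50: {n_hypo}/50 hypomethylate with age in intact males")

universe = list(dataset.beta.index)
chrom = oc.chrom_distribution(top50, dataset.annotation, universe)
print(f"chromosomal spread of top 50: chi2 = {chrom['chi2']:.1f}, "
      f"p = {chrom['p']:.3f} (high p = spread like the array background)")

enr = oc.enrich(top50, tf_table, dataset.annotation, universe,
                n_boot=1000, seed=5)
print("\nTF binding at top 50 vs bootstrap expectation:")
cols = ["observed_pct", "expected_pct", "fold", "p_emp", "flagged"]
print(enr.sort_values("fold", ascending=False)[cols].head(4).round(3))
print()
flagged = oc.flag(enr)
print(f"flagged factors (fold>2 and |obs-exp|>1%): "
      f"{list(flagged['tf_name'])}")
print("Only the AR-like factor was planted on asDMP probes; its empirical p")
print("sits at the 1/1001 floor. Background factors can cross the 2-fold")
print("flag line by chance at k=50, but none approaches AR's ratio or p.")
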