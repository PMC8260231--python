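"""Screen every probe for age-associated methylation.

Correlates each probe's beta values with chronological age, reports the
strongest hits and the global methylation trend, and compares tissue strata.
"""

import ovisclock as oc

dataset, _, truth = oc.simulate_dataset(oc.SimConfig(
    n_samples=300, n_probes=1000, n_clock_probes=60, n_asdmp_probes=0,
    seed=7))

results = oc.screen_age(dataset, method="pearson")
top = results.sort_values("p").head(5)
print("top age-associated probes (r = Pearson correlation with age):")
print(top[["probe_id", "r", "n", "t", "p"]].to_string(index=False))

n_sig = (results["p"] < 1e-6).sum()
hits = set(results.loc[results["p"] < 1e-6, "probe_id"])
planted = set(truth.index[truth["role"] == "clock"])
print(f"\nprobes at p < 1e-6: {n_sig} "
      f"({len(hits & planted)} of them planted age-responsive)")

trend = oc.global_trend(dataset)
print(f"\nglobal trend: mean beta changes {trend['slope']:+.5f}/year "
      f"(p = {trend['p']:.3g})")

by_tissue = {t: oc.screen_age(dataset, stratum=f"tissue == '{t}'")
             for t in ("ear", "blood")}
shared = oc.strata_overlap(by_tissue, p_threshold=1e-4)
print(f"significant probes shared between tissues at p<1e-4: "
      f"{shared[('blood', 'ear')]} "
      f"(ear alone {shared[('ear',)]}, blood alone {shared[('blood',)]})")
print()
print("A planted age slope of 0.1 logit/yr against 0.3 logit noise makes")
print("age-responsive probes clearly separable from the null background.")
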