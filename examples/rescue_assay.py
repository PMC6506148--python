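"""Scoring a rescue-from-lethality assay from raw vial counts.

Simulates triplicate vials (P = 100 pupal cases each, adults binomial)
for vehicle, two single-drug arms and their combination in the lethal
model genotype plus wild-type toxicity controls, then computes per-arm
viability, one-sided rescue tests against vehicle, the >90% wild-type
toxicity gate, and a synergy verdict for the combination.
"""

from kinscreen import (
    SimConfig,
    rescue_test,
    simulate_assay,
    synergy_call,
    toxicity_check,
    viability_by_condition,
)

records = simulate_assay(SimConfig(seed=17))
model_arms = viability_by_condition(records, genotype="model")
vehicle = model_arms.pop("vehicle")

results = {}
for condition, reps in model_arms.items():
    res = rescue_test(reps, vehicle, condition=condition, control_label="vehicle")
    results[condition] = res
    star = " *" if res.significant else ""
    print(f"{condition:14s} viability {res.mean_viability:5.1f}% "
          f"(t={res.t_statistic:5.2f}, one-sided p={res.p_one_sided:.4f}){star}")

controls = [r for r in records if r.genotype == "control"]
gate = toxicity_check(controls, threshold=90.0)
print("toxicity gate (wild-type >90% in every vial):",
      {c: "pass" if ok else "FAIL" for c, ok in gate.items()})

verdict = synergy_call(results["drug_A+drug_B"], results["drug_A"], results["drug_B"])
print(f"combination verdict: {verdict} "
      f"(combo {results['drug_A+drug_B'].mean_viability:.1f}% vs "
      f"{results['drug_A'].mean_viability:.1f}% + {results['drug_B'].mean_viability:.1f}%)")
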