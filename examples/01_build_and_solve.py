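"""Build the synthetic bacteroid model and maximise nitrogen export.

The generator assembles a ~70-reaction nodule bacteroid: plant-supplied
malate and glutamate in, fixed nitrogen (ammonia, alanine, aspartate) out,
with the coupled nutrient-sharing / nitrogenase objective already attached.
"""

from snfba import generate_toy_snf_model, solve_fba, summarize_model

model, truth = generate_toy_snf_model()
print(summarize_model(model).pretty())

solution = solve_fba(model)
print(f"\nstatus: {solution.status}")
print(f"SNF objective (nutrient-sharing flux): "
      f"{solution.objective_value:.4f} mmol/gDW/hr")
for rid, label in [("NASE", "nitrogenase"),
                   ("EX_mal_e", "malate uptake"),
                   ("EX_glu_e", "glutamate exchange"),
                   ("EX_o2_e", "oxygen uptake"),
                   ("EX_nh3_e", "ammonia export")]:
    print(f"  {label:20s} {solution.fluxes[rid]:+8.4f}")

print("\nEach unit of objective flux exports one ammonia, one alanine and "
      "one aspartate\nto the plant; negative exchange fluxes are uptake. "
      "Nitrogenase runs at half the\nobjective rate because each turnover "
      "fixes two ammonia.")
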