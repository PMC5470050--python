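"""Simulate two alcocyte incubations and compare with the measured rates.

The first experiment supplies a large pyruvate excess (60 mM bolus), so
NADH reoxidation by LDH never limits the flux; the second relies on
glycolysis alone (a constant pyruvate influx of 3.6 mmol/l_RBCs·h), which
caps the sustainable ethanol oxidation at half that supply.
"""

from alcocyte import run_scenario

for name in ("pyruvate_bolus_60mM", "glycolysis_only"):
    res = run_scenario(name)
    sim = res.metrics["initial_rate"].value
    measured = res.preset.measured_initial_rate
    print(f"\n{name}")
    print(f"  {res.preset.provenance}")
    print(f"  simulated initial rate: {sim:6.2f} mmol/l_RBCs·h  (measured: {measured})")
    eth = res.timecourse.data.ethanol_mM
    print(f"  ethanol after 5 h: {eth.iloc[-1]:.2f} mM of {eth.iloc[0]:.0f} mM")

print(
    "\nWith excess pyruvate the model sustains tens of mmol/l_RBCs·h; on "
    "glycolytic supply alone it plateaus at V_in/2 = 1.8 mmol/l_RBCs·h — the "
    "cofactor cycle, not the loaded enzymes, sets the ceiling."
)
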