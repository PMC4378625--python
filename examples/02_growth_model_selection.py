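"""Fit candidate growth models to simulated cohorts and select the best.

Four variety x watering groups of 14 plants are simulated from the
3-parameter logistic with 5% multiplicative noise (the sigmoidal
watering-trial design).  Candidates failing to converge on any group are
disqualified; survivors are ranked by mean AIC with parsimony and
prediction-band tie-breaks.  The winner's inflection time (the day of
maximum absolute growth rate) and fitted rates are then derived.
"""

import numpy as np

from phenoshoot import growth, synthetic

groups = {}
for gi, (name, params) in enumerate(synthetic.WATERING_TRIAL_GROUPS.items()):
    series = synthetic.generate_growth_series(
        synthetic.TrajectorySpec("logistic3", params, tuple(range(18, 48)), 0.05, 14, seed=gi)
    )
    groups[name] = (np.concatenate([s.times for s in series]),
                    np.concatenate([s.values for s in series]))

sel = growth.select_model(groups, ["logistic3", "gompertz", "exponential", "power_law"], seed=0)
print(sel.table.to_string(index=False))
print(f"\nselected model: {sel.best}  (lowest mean AIC after the robustness screen)\n")

for name in groups:
    f = sel.fits[(sel.best, name)]
    t_inf = growth.inflection_time(f)
    curves = growth.growth_curves(f, np.linspace(18, 47, 30), n_draws=1000, seed=1)
    i = np.argmax(curves.AGR)
    print(f"{name:10s}  Asym={f.estimates['Asym']:7.0f} mm^2  "
          f"inflection day {t_inf:5.1f}  peak AGR {curves.AGR[i]:6.1f} mm^2/d  "
          f"RGR(day 20) {growth.rgr(f.model_name, f.params, 20.0):.3f} /d")
print("\nWater-limited groups plateau lower and peak ~10 days earlier than")
print("well-watered ones; the 95% bands come from 1000 parameter draws.")
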