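"""Build a task session, simulate an agent, and invert the model.

The session is 4 alternating physical/mental blocks of 54 trials. The
agent weighs monetary incentives against effort costs with known
sensitivities; the MAP fit should land near those values.
"""

import numpy as np

from effortpath import ModelParams, TaskConfig, fit_map, generate_session, \
    simulate_choices

params = ModelParams(kR=1.0, kP=1.0, kEp=0.8, kEm=0.5,
                     kFp=0.8, kLm=0.3, kBias=0.1)
session = generate_session(TaskConfig(), first_domain="physical", seed=1)
choices = simulate_choices(session, params, np.random.default_rng(2))

phys = choices["domain"] == "physical"
print(f"trials simulated:        {len(choices)}")
print(f"high-effort choice rate: {choices['choice'].mean():.3f} "
      f"(physical {choices.loc[phys, 'choice'].mean():.3f}, "
      f"mental {choices.loc[~phys, 'choice'].mean():.3f})")

fit = fit_map(choices, seed=0)
print("\nparameter   true   recovered")
for name in ("kR", "kP", "kEp", "kEm", "kFp", "kLm", "kBias"):
    print(f"{name:<10} {getattr(params, name):6.3f} "
          f"{getattr(fit.estimates, name):10.3f}")
print(f"\nlog evidence (Laplace): {fit.laplace_evidence:.2f}")
print("Recovered sensitivities should sit near the generating values;")
print("kFp/kLm are weakly identified from a single 216-trial session.")
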