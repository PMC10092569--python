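"""Walk through one simulated trial per design on the cliff scenario.

Scenario D (cycle-1 DLT probabilities .05/.05/.05/.80/.80/.80) separates
three clearly safe doses from three clearly unsafe ones; the third dose
is the MTD.  The same replicate (same latent patients) is run under
every design to show how differently they navigate the cliff.
"""

from pathlib import Path

import pandas as pd

from latedose import DESIGN_NAMES, TrialConfig, builtin_scenario, default_design, run_trial

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

scenario = builtin_scenario("D")
config = TrialConfig()
rows = []
for name in DESIGN_NAMES:
    res = run_trial(default_design(name, 1), scenario, config, base_seed=1,
                    replicate=0)
    rows.append({
        "design": name,
        "patients": res.n_patients,
        "duration_weeks": res.duration_weeks,
        "recommended_dose": None if res.recommendation is None
        else res.recommendation + 1,
        "correct": res.recommendation == 2,
        "allocation": "/".join(map(str, res.allocation)),
        "stop_reasons": ";".join(res.stop_reasons),
    })
df = pd.DataFrame(rows)
df.to_csv(OUT / "03_trial_walkthrough.csv", index=False)
print(df.to_string(index=False))
print("\nAll designs see the same latent patients; they differ in how "
      "quickly they retreat from the unsafe fourth dose and settle on "
      "dose 3 (3.5 MBq).")
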