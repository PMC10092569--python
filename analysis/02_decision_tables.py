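"""Precompute the interval designs' boundaries and decision tables.

Model-assisted designs act through lookup tables fixed before the
trial; this script exports the BOIN boundaries and the complete-data
decision tables of the keyboard family, plus a TITE-BOIN table over
pending-patient configurations at cohort resolution.
"""

from pathlib import Path

import pandas as pd

from latedose import BetaPrior, IntervalSpec, boin_thresholds
from latedose.boin import titeboin_decision
from latedose.keyboard import keyboard_decision

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

BOIN_IV = IntervalSpec(0.391, 0.3128, 0.5083)
MTPI_IV = IntervalSpec(0.391, 0.3519, 0.5474)
lam_e, lam_d = boin_thresholds(BOIN_IV)
print(f"BOIN boundaries for target 0.391: lambda_e={lam_e:.4f}, "
      f"lambda_d={lam_d:.4f}")

rows = []
for n in range(1, 13):
    for m in range(n + 1):
        rate = m / n
        boin = ("escalate" if rate <= lam_e
                else "de-escalate" if rate >= lam_d else "stay")
        kb = keyboard_decision(float(n), float(m), BetaPrior(1, 1), MTPI_IV).value
        rows.append({"n": n, "dlt": m, "boin": boin, "keyboard": kb})
pd.DataFrame(rows).to_csv(OUT / "02_complete_data_tables.csv", index=False)

# TITE-BOIN over pending configurations (cohort resolution, S = 3)
rows = []
for n in (3, 6, 9):
    for m in range(n + 1):
        for pend in range(0, n - m + 1):
            for k_obs in (1, 2):  # cycles observed per pending patient
                stft = pend * k_obs / 3
                s = {"n": n, "dlt": m, "complete": n - m - pend,
                     "pending": pend, "stft": stft}
                move = titeboin_decision(s, (lam_e, lam_d), BetaPrior(0.1, 0.9))
                rows.append({**{k: s[k] for k in ("n", "dlt", "pending")},
                             "cycles_per_pending": k_obs, "stft": round(stft, 3),
                             "move": move.value})
df = pd.DataFrame(rows)
df.to_csv(OUT / "02_titeboin_pending_table.csv", index=False)
print(f"wrote {len(df)} TITE-BOIN pending-configuration rows; "
      "decisions reduce to plain BOIN whenever pending = 0.")
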