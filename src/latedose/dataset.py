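"""Interim trial data: the view of enrolled patients available at a decision.

A :class:`ToxDataset` holds, for every enrolled patient whose first cycle
has completed, the assigned dose, the number of cycles observed so far
``u``, the DLT indicator/cycle, and per observed cycle the three-level
ordinal toxicity category (1: grade <=1, 2: grade 2, 3: grade >=3), the
maximum grade and the nTTP score.  No outcomes are stored for cycles
after a DLT (the patient leaves the study).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["PatientRecord", "ToxDataset"]


@dataclass(frozen=True)
class PatientRecord:
    patient: int
    dose: int  # 0-based dose index
    dose_value: float
    cycles_observed: int  # u, number of cycles with data
    dlt_cycle: int | None  # 1-based, None if no DLT observed
    categories: tuple[int, ...]  # per observed cycle, in {1, 2, 3}
    max_grades: tuple[int, ...]
    nttp: tuple[float, ...]

    def __post_init__(self) -> None:
        u = self.cycles_observed
        if len(self.categories) != u or len(self.nttp) != u:
            raise ValueError("per-cycle outcomes must match cycles_observed")
        if self.dlt_cycle is not None:
            if self.dlt_cycle != u:
                raise ValueError("a DLT ends follow-up: dlt_cycle must equal u")
            if self.categories[-1] != 3:
                raise ValueError("DLT cycle must carry category 3")
        if any(c == 3 for c in self.categories[:-1]):
            raise ValueError("category 3 before the final observed cycle")

    @property
    def dlt(self) -> bool:
        return self.dlt_cycle is not None


@dataclass(frozen=True)
class ToxDataset:
    """All data observable at one decision time."""

    records: tuple[PatientRecord, ...]
    n_cycles: int  # full follow-up length S
    dose_values: tuple[float, ...]

    @property
    def n_patients(self) -> int:
        return len(self.records)

    @property
    def n_doses(self) -> int:
        return len(self.dose_values)

    def treated_per_dose(self) -> np.ndarray:
        out = np.zeros(self.n_doses, dtype=int)
        for r in self.records:
            out[r.dose] += 1
        return out

    def dlt_per_dose(self) -> np.ndarray:
        out = np.zeros(self.n_doses, dtype=int)
        for r in self.records:
            out[r.dose] += int(r.dlt)
        return out

    def cycle1_counts(self) -> tuple[np.ndarray, np.ndarray]:
        """Per dose: (patients with cycle 1 observed, cycle-1 DLTs)."""
        n = np.zeros(self.n_doses, dtype=int)
        dlt = np.zeros(self.n_doses, dtype=int)
        for r in self.records:
            if r.cycles_observed >= 1:
                n[r.dose] += 1
                dlt[r.dose] += int(r.dlt_cycle == 1)
        return n, dlt

    def interval_counts(self) -> tuple[np.ndarray, np.ndarray]:
        """Interval-censored counts ``(r[j,s], q[j,s])``.

        ``r[j,s]``: patients on dose j with a DLT in cycle s+1 (0-based s);
        ``q[j,s]``: patients who completed cycle s+1 on dose j without DLT.
        """
        r = np.zeros((self.n_doses, self.n_cycles))
        q = np.zeros((self.n_doses, self.n_cycles))
        for rec in self.records:
            for s in range(1, rec.cycles_observed + 1):
                if rec.dlt_cycle == s:
                    r[rec.dose, s - 1] += 1
                else:
                    q[rec.dose, s - 1] += 1
        return r, q

    def pending_summary(self, dose: int) -> dict:
        """Interim follow-up summary at one dose for interval designs.

        ``pending`` counts DLT-free patients whose follow-up is
        incomplete; ``stft`` is their summed follow-up fraction u/S.
        """
        n = m = c = pend = 0
        stft = 0.0
        for rec in self.records:
            if rec.dose != dose:
                continue
            n += 1
            if rec.dlt:
                m += 1
            elif rec.cycles_observed >= self.n_cycles:
                c += 1
            else:
                pend += 1
                stft += rec.cycles_observed / self.n_cycles
        return {"n": n, "dlt": m, "complete": c, "pending": pend, "stft": stft}

    def to_frame(self) -> pd.DataFrame:
        """One row per patient-cycle, for audit/CSV export."""
        rows = []
        for rec in self.records:
            for s in range(1, rec.cycles_observed + 1):
                rows.append(
                    {
                        "patient": rec.patient,
                        "dose": rec.dose + 1,
                        "dose_value": rec.dose_value,
                        "cycle": s,
                        "category": rec.categories[s - 1],
                        "max_grade": rec.max_grades[s - 1],
                        "nttp": rec.nttp[s - 1],
                        "dlt": int(rec.dlt_cycle == s),
                    }
                )
        return pd.DataFrame(
            rows,
            columns=[
                "patient",
                "dose",
                "dose_value",
                "cycle",
                "category",
                "max_grade",
                "nttp",
                "dlt",
            ],
        )
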