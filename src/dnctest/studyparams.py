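"""Published cohort statistics for the mouse DNC Test study.

The Dopamine Neuron Challenge (DNC) Test measures dopamine metabolites in
CSF and plasma after pharmacologically evoked dopamine release
(methylphenidate 10 mg/kg + haloperidol 1 mg/kg, i.p.).  Two disease
stages were characterised in the MitoPark genetic mouse model of
Parkinson's disease:

* ``early`` — 20-week-old MitoPark mice with ~28% loss of substantia
  nigra dopamine neurons versus littermate controls.
* ``ultra_early`` — 15-week-old MitoPark mice with no detectable neuron
  loss but ~44% loss of TH+ axonal terminals in the dorsal striatum.

Only group-level summaries (mean, SEM, n) were published; these tables
parameterise the synthetic-cohort generator and the closed-form
performance predictions.  CSF analytes are expressed as peak-area ratios
against the serotonin metabolite 5-HIAA (an internal control that cancels
dilution errors from the 2-5 ul CSF volumes); plasma HVA is an absolute
concentration in ng/ml via an HVA standard curve.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "GroupStats",
    "ANALYTES",
    "ANALYTE_MATRIX",
    "STAGES",
    "GROUPS",
    "STATES",
    "COHORT_STATS",
    "CELL_COUNTS",
    "TERMINAL_DENSITY",
    "STANDARD_CONCENTRATIONS_NG_ML",
    "PUBLISHED_PERFORMANCE",
]


@dataclass(frozen=True)
class GroupStats:
    """Mean +/- SEM summary of one (group, state) cell with sample size n."""

    mean: float
    sem: float
    n: int

    @property
    def sd(self) -> float:
        """Population SD implied by the SEM: SD = SEM * sqrt(n)."""
        return self.sem * math.sqrt(self.n)


GROUPS = ("control", "PD")
STATES = ("resting", "challenged")
STAGES = ("early", "ultra_early")

#: analyte identifiers used throughout the cohort-table schema
ANALYTES = ("DOPAC_5HIAA", "HVA_5HIAA", "HVA_ng_ml")

#: body-fluid matrix each analyte is measured in
ANALYTE_MATRIX = {
    "DOPAC_5HIAA": "CSF",
    "HVA_5HIAA": "CSF",
    "HVA_ng_ml": "plasma",
}

#: (stage, analyte, group, state) -> GroupStats for the MitoPark cohorts
COHORT_STATS: dict[tuple[str, str, str, str], GroupStats] = {
    # ---- early stage: 20-week-old MitoPark vs littermate control ----
    ("early", "DOPAC_5HIAA", "control", "resting"): GroupStats(9.22e-2, 4.96e-3, 11),
    ("early", "DOPAC_5HIAA", "PD", "resting"): GroupStats(8.07e-2, 5.96e-3, 6),
    ("early", "DOPAC_5HIAA", "control", "challenged"): GroupStats(1.52e-1, 6.21e-3, 14),
    ("early", "DOPAC_5HIAA", "PD", "challenged"): GroupStats(6.94e-2, 4.14e-3, 12),
    ("early", "HVA_5HIAA", "control", "resting"): GroupStats(6.71e-2, 4.93e-3, 11),
    ("early", "HVA_5HIAA", "PD", "resting"): GroupStats(4.84e-2, 6.15e-3, 6),
    ("early", "HVA_5HIAA", "control", "challenged"): GroupStats(1.65e-1, 8.92e-3, 14),
    ("early", "HVA_5HIAA", "PD", "challenged"): GroupStats(6.90e-2, 3.50e-3, 12),
    ("early", "HVA_ng_ml", "control", "resting"): GroupStats(8.35, 0.31, 21),
    ("early", "HVA_ng_ml", "PD", "resting"): GroupStats(6.62, 0.35, 22),
    ("early", "HVA_ng_ml", "control", "challenged"): GroupStats(17.91, 1.04, 22),
    ("early", "HVA_ng_ml", "PD", "challenged"): GroupStats(9.39, 0.46, 13),
    # ---- ultra-early stage: 15-week-old MitoPark vs littermate control ----
    ("ultra_early", "DOPAC_5HIAA", "control", "resting"): GroupStats(7.46e-2, 2.24e-3, 14),
    ("ultra_early", "DOPAC_5HIAA", "PD", "resting"): GroupStats(6.97e-2, 2.75e-3, 8),
    ("ultra_early", "DOPAC_5HIAA", "control", "challenged"): GroupStats(1.29e-1, 5.27e-3, 20),
    ("ultra_early", "DOPAC_5HIAA", "PD", "challenged"): GroupStats(7.88e-2, 6.03e-3, 11),
    ("ultra_early", "HVA_5HIAA", "control", "resting"): GroupStats(8.13e-2, 2.92e-3, 14),
    ("ultra_early", "HVA_5HIAA", "PD", "resting"): GroupStats(7.22e-2, 3.21e-3, 8),
    ("ultra_early", "HVA_5HIAA", "control", "challenged"): GroupStats(1.87e-1, 8.37e-3, 20),
    ("ultra_early", "HVA_5HIAA", "PD", "challenged"): GroupStats(1.20e-1, 7.68e-3, 11),
    ("ultra_early", "HVA_ng_ml", "control", "resting"): GroupStats(5.58, 0.39, 19),
    ("ultra_early", "HVA_ng_ml", "PD", "resting"): GroupStats(5.28, 0.36, 13),
    ("ultra_early", "HVA_ng_ml", "control", "challenged"): GroupStats(16.37, 0.60, 47),
    ("ultra_early", "HVA_ng_ml", "PD", "challenged"): GroupStats(12.21, 0.49, 25),
}

#: TH+ cell counts per brain (11 evenly spaced coronal sections each)
CELL_COUNTS = {
    # 20-week MitoPark: 28% neuron loss
    ("early", "control"): GroupStats(8252.0, 204.0, 11),
    ("early", "PD"): GroupStats(5914.0, 213.0, 8),
    # 15-week MitoPark: no significant loss yet
    ("ultra_early", "control"): GroupStats(7830.0, 168.0, 11),
    ("ultra_early", "PD"): GroupStats(7618.0, 115.0, 5),
    # unilateral intrastriatal 6-OHDA lesion, per-side counts (n=15 mice)
    ("6ohda", "intact_side"): GroupStats(4125.0, 140.1, 15),
    ("6ohda", "lesioned_side"): GroupStats(1760.0, 104.6, 15),
}

#: TH+ terminal optical density in dorsal striatum (arbitrary density units)
TERMINAL_DENSITY = {
    ("ultra_early", "control"): GroupStats(1823.0, 186.0, 12),
    ("ultra_early", "PD"): GroupStats(1023.0, 89.0, 6),
}

#: HVA reference-standard concentrations for the plasma calibration curve
STANDARD_CONCENTRATIONS_NG_ML = (0.5, 1.0, 5.0, 10.0, 20.0, 30.0, 40.0, 50.0)

#: published classifier performance per (stage, analyte):
#: (true positives, total PD, true negatives, total control)
PUBLISHED_PERFORMANCE = {
    ("early", "DOPAC_5HIAA"): (12, 12, 14, 14),
    ("early", "HVA_5HIAA"): (12, 12, 14, 14),
    ("early", "HVA_ng_ml"): (13, 13, 18, 22),
    ("ultra_early", "DOPAC_5HIAA"): (10, 11, 17, 20),
    ("ultra_early", "HVA_5HIAA"): (10, 11, 16, 20),
    ("ultra_early", "HVA_ng_ml"): (19, 25, 28, 47),
}
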