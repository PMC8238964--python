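"""Published reference cohort summary for dermal microvasculature.

Cohort-mean metric values (mean and SD) for healthy female subjects
quantified with conventional OCT-A, reactive-hyperemia OCT-A and
CD31-stained horizontal histology over 6 x 6 mm forearm fields,
stratified by age band (young 18-30 y, old >= 65 y) and resting
systolic blood pressure (< 130 vs >= 130 mmHg). These serve as worked
examples for the metric arithmetic — in particular the mean vessel
diameter VD/LVN — and as a shape template for synthetic cohorts; the
subject-level data behind them are not public.

Units: vd percent, lvn mm/mm^2, nbp count per field, diameter um.
``diameter_um`` is the published per-cohort figure, which averaged
per-image diameters; ``ratio_diameter_um`` (the helper) recomputes it
as the ratio of cohort means, which matches the published value after
rounding for some rows and differs by <= 0.3 um for the others.
"""

from __future__ import annotations

from dataclasses import dataclass

from .metrics import mean_vessel_diameter

#: Cohort sizes (subjects per group).
COHORT_N = {"young": 13, "old": 12, "lt130": 15, "ge130": 10}

#: Published mean RCC per cohort, as fractions (printed as percent).
REFERENCE_RCC = {"young": 2.21, "old": 1.46, "lt130": 2.29, "ge130": 1.17}


@dataclass(frozen=True)
class ReferenceRow:
    """One (method, cohort) row of the published summary table."""

    method: str  # octa | rh_octa | histology
    cohort: str  # young | old | lt130 | ge130
    vd: float
    vd_sd: float
    lvn: float
    lvn_sd: float
    nbp: float
    nbp_sd: float
    diameter_um: float
    diameter_sd: float

    @property
    def n(self) -> int:
        return COHORT_N[self.cohort]

    @property
    def ratio_diameter_um(self) -> float:
        """Mean vessel diameter recomputed from the cohort-mean VD and LVN."""
        return mean_vessel_diameter(self.vd, self.lvn)


REFERENCE_COHORTS: tuple[ReferenceRow, ...] = (
    ReferenceRow("octa", "young", 22.7, 2.0, 7.2, 0.6, 2275, 320, 31.7, 2.7),
    ReferenceRow("octa", "old", 21.2, 2.5, 7.1, 0.8, 2320, 370, 29.7, 2.0),
    ReferenceRow("octa", "lt130", 21.9, 2.5, 7.1, 0.8, 2250, 330, 30.8, 2.7),
    ReferenceRow("octa", "ge130", 21.9, 2.8, 7.2, 0.8, 2330, 340, 30.6, 2.6),
    ReferenceRow("rh_octa", "young", 30.7, 1.7, 10.2, 0.8, 3730, 440, 30.4, 1.9),
    ReferenceRow("rh_octa", "old", 26.9, 3.3, 9.4, 1.4, 3245, 660, 28.6, 2.0),
    ReferenceRow("rh_octa", "lt130", 30.0, 2.6, 10.2, 0.8, 3710, 460, 29.6, 2.2),
    ReferenceRow("rh_octa", "ge130", 26.9, 3.1, 9.2, 1.2, 3095, 575, 29.5, 2.2),
    ReferenceRow("histology", "young", 27.4, 4.8, 12.3, 1.7, 5895, 1025, 22.3, 2.6),
    ReferenceRow("histology", "old", 24.3, 5.4, 11.1, 2.0, 5065, 1205, 22.0, 2.5),
    ReferenceRow("histology", "lt130", 27.6, 4.7, 12.3, 1.7, 5940, 1075, 22.3, 2.3),
    ReferenceRow("histology", "ge130", 23.2, 5.3, 10.6, 1.7, 4838, 1070, 21.8, 2.9),
)


def reference_row(method: str, cohort: str) -> ReferenceRow:
    """Look up one (method, cohort) row; KeyError if absent."""
    for row in REFERENCE_COHORTS:
        if row.method == method and row.cohort == cohort:
            return row
    raise KeyError(f"no reference row for method={method!r} cohort={cohort!r}")
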