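"""Deterministic diagnostic rule engine for iron-overload cohorts.

Encodes the glucose-metabolism classes (NGT/IFG/IGT/DM from fasting and
2-h OGTT glucose), HOMA-IR, the organ iron/fat thresholds (pancreas T2*
< 26 ms, FF above the normative limit, LIC >= 3 mg/g dw, heart T2* <= 20
ms), the metabolic-syndrome majority rule (>= 3 of 5 criteria), cardiac
complications (heart failure, documented arrhythmia, pulmonary
hypertension from a tricuspid jet > 3.2 m/s), and the ventricular
stroke-volume/ejection-fraction arithmetic.

Boundary conventions follow the clinical definitions exactly as written:
pancreatic iron overload is *strict* T2* < 26 ms, hepatic iron is
*non-strict* LIC >= 3, myocardial iron is pathological at T2* <= 20 ms
(normal is strictly above 20), and PH needs a jet strictly above 3.2 m/s.

Missing data propagate as ``None`` (unknown); nothing is imputed, and a
three-valued verdict is only committed when no completion of the unknown
inputs could change it.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

from .roi_mapping import CardiacT2StarMap, LiverMeasurement, PancreasMeasurement

__all__ = [
    "GlucoseClass",
    "GlucoseThresholds",
    "MetabolicCriteria",
    "DiagnosticFlags",
    "PatientRecord",
    "classify_glucose",
    "homa_ir",
    "flag_iron_and_fat",
    "classify_metabolic_syndrome",
    "classify_cardiac_complication",
    "ventricular_indices",
    "PANCREAS_T2S_NORMAL_MS",
    "FF_UPPER_LIMIT_PCT",
    "LIC_SIGNIFICANT_MG_G",
    "HEART_T2S_NORMAL_MS",
    "JET_VELOCITY_PH_M_S",
    "HOMA_DENOMINATOR",
]

PANCREAS_T2S_NORMAL_MS = 26.0   # lowest normal pancreatic T2*; overload if strictly below
FF_UPPER_LIMIT_PCT = 6.6        # normative upper limit of pancreatic FF (injectable)
LIC_SIGNIFICANT_MG_G = 3.0      # significant hepatic iron if LIC >= this
HEART_T2S_NORMAL_MS = 20.0      # conservative normal; pathological if <= this
JET_VELOCITY_PH_M_S = 3.2       # pulmonary hypertension if jet strictly above
HOMA_DENOMINATOR = 405.0


class GlucoseClass(enum.StrEnum):
    NGT = "NGT"
    IFG = "IFG"
    IGT = "IGT"
    DM = "DM"
    UNKNOWN = "unknown"


@dataclass(frozen=True)
class GlucoseThresholds:
    """OGTT thresholds in mg/dL."""

    fpg_ifg: float = 100.0
    fpg_dm: float = 126.0
    g2h_igt: float = 140.0
    g2h_dm: float = 200.0


def classify_glucose(
    fpg_mg_dl: float,
    glucose_2h_mg_dl: float | None = None,
    known_diabetes: bool = False,
    thresholds: GlucoseThresholds = GlucoseThresholds(),
) -> GlucoseClass:
    """Classify glucose metabolism from fasting and 2-h OGTT glucose.

    Classes are mutually exclusive with precedence DM > IGT > IFG > NGT:
    DM if known diabetes, FPG >= 126, or 2h >= 200; else IGT if
    140 <= 2h < 200; else IFG if 100 <= FPG < 126; else NGT.  A missing
    2-h value yields ``UNKNOWN`` unless the class is already determined
    from the fasting value or the known-diabetes flag.
    """
    if fpg_mg_dl is None:
        raise ValueError("fasting plasma glucose is required")
    if fpg_mg_dl < 0 or (glucose_2h_mg_dl is not None and glucose_2h_mg_dl < 0):
        raise ValueError("glucose values must be non-negative")
    t = thresholds
    if known_diabetes or fpg_mg_dl >= t.fpg_dm:
        return GlucoseClass.DM
    if glucose_2h_mg_dl is None:
        return GlucoseClass.UNKNOWN
    if glucose_2h_mg_dl >= t.g2h_dm:
        return GlucoseClass.DM
    if glucose_2h_mg_dl >= t.g2h_igt:
        return GlucoseClass.IGT
    if fpg_mg_dl >= t.fpg_ifg:
        return GlucoseClass.IFG
    return GlucoseClass.NGT


def homa_ir(glucose_mg_dl: float, insulin_uu_ml: float) -> float:
    """HOMA insulin-resistance index: (fasting glucose x fasting insulin) / 405.

    Intended for non-diabetic subjects (usage contract; not enforced
    numerically).
    """
    if glucose_mg_dl < 0 or insulin_uu_ml < 0:
        raise ValueError("glucose and insulin must be non-negative")
    return glucose_mg_dl * insulin_uu_ml / HOMA_DENOMINATOR


@dataclass(frozen=True)
class MetabolicCriteria:
    """Inputs of the five metabolic-syndrome criteria; any may be missing.

    Criteria (true/false/unknown each):
      1. waist >= 102 cm (men) / >= 88 cm (women);
      2. HDL < 40 (men) / < 50 (women) mg/dL, or on lipid treatment;
      3. triglycerides >= 150 mg/dL, or on treatment;
      4. SBP >= 130 or DBP >= 85 mmHg, or on anti-hypertensives;
      5. FPG >= 100 mg/dL, or on diabetes treatment.
    """

    sex: str | None = None  # "M" | "F"
    waist_cm: float | None = None
    hdl_mg_dl: float | None = None
    lipid_treatment: bool | None = None
    triglycerides_mg_dl: float | None = None
    tg_treatment: bool | None = None
    sbp_mmhg: float | None = None
    dbp_mmhg: float | None = None
    bp_treatment: bool | None = None
    fpg_mg_dl: float | None = None
    diabetes_treatment: bool | None = None

    def resolve(self) -> tuple[bool | None, ...]:
        """Each criterion as True / False / None (unknown)."""
        return (
            self._waist(),
            self._or(self._hdl(), self.lipid_treatment),
            self._or(
                None if self.triglycerides_mg_dl is None else self.triglycerides_mg_dl >= 150,
                self.tg_treatment,
            ),
            self._or(self._bp(), self.bp_treatment),
            self._or(
                None if self.fpg_mg_dl is None else self.fpg_mg_dl >= 100,
                self.diabetes_treatment,
            ),
        )

    def _waist(self) -> bool | None:
        if self.waist_cm is None or self.sex not in ("M", "F"):
            return None
        return self.waist_cm >= (102.0 if self.sex == "M" else 88.0)

    def _hdl(self) -> bool | None:
        if self.hdl_mg_dl is None or self.sex not in ("M", "F"):
            return None
        return self.hdl_mg_dl < (40.0 if self.sex == "M" else 50.0)

    def _bp(self) -> bool | None:
        if self.sbp_mmhg is None and self.dbp_mmhg is None:
            return None
        high_s = None if self.sbp_mmhg is None else self.sbp_mmhg >= 130
        high_d = None if self.dbp_mmhg is None else self.dbp_mmhg >= 85
        return self._or(high_s, high_d)

    @staticmethod
    def _or(a: bool | None, b: bool | None) -> bool | None:
        # three-valued OR: True dominates, unknown beats False
        if a is True or b is True:
            return True
        if a is None or b is None:
            return None
        return False


def classify_metabolic_syndrome(criteria: MetabolicCriteria) -> bool | None:
    """Metabolic syndrome iff at least 3 of the 5 criteria hold.

    Returns ``None`` when the unknown criteria could still change the
    verdict (monotone three-valued majority).
    """
    resolved = criteria.resolve()
    n_true = sum(1 for c in resolved if c is True)
    n_unknown = sum(1 for c in resolved if c is None)
    if n_true >= 3:
        return True
    if n_true + n_unknown < 3:
        return False
    return None


def classify_cardiac_complication(
    heart_failure: bool | None,
    arrhythmia: bool | None,
    jet_velocity_m_s: float | None,
    jet_threshold_m_s: float = JET_VELOCITY_PH_M_S,
) -> tuple[bool | None, frozenset[str]]:
    """Cardiac complication = heart failure, arrhythmia, or PH.

    Heart failure and arrhythmia are clinician-supplied flags; pulmonary
    hypertension is derived from the trans-tricuspid jet velocity
    (strictly above 3.2 m/s).  Returns (flag, subtype set); the flag is
    ``None`` when no subtype is established and at least one input is
    unknown.
    """
    ph = None if jet_velocity_m_s is None else jet_velocity_m_s > jet_threshold_m_s
    subtypes = set()
    if heart_failure:
        subtypes.add("HF")
    if arrhythmia:
        subtypes.add("arrhythmia")
    if ph:
        subtypes.add("PH")
    if subtypes:
        return True, frozenset(subtypes)
    if heart_failure is None or arrhythmia is None or ph is None:
        return None, frozenset()
    return False, frozenset()


def ventricular_indices(edvi_ml_m2: float, esvi_ml_m2: float) -> tuple[float, float]:
    """Stroke volume index and ejection fraction from EDVI/ESVI.

    SVI = EDVI - ESVI (mL/m^2); EF = 100 * SVI / EDVI (%).
    """
    if edvi_ml_m2 <= 0:
        raise ValueError("EDVI must be positive")
    if esvi_ml_m2 < 0 or esvi_ml_m2 > edvi_ml_m2:
        raise ValueError("ESVI must lie in [0, EDVI]")
    svi = edvi_ml_m2 - esvi_ml_m2
    return svi, 100.0 * svi / edvi_ml_m2


@dataclass(frozen=True)
class DiagnosticFlags:
    """Derived diagnostic flags; ``None`` marks an undeterminable flag."""

    pancreatic_iron_overload: bool | None = None
    pancreatic_fatty_replacement: bool | None = None
    significant_hepatic_iron: bool | None = None
    significant_mio: bool | None = None
    n_pathological_segments: int | None = None
    glucose_class: GlucoseClass | None = None
    metabolic_syndrome: bool | None = None
    cardiac_complication: bool | None = None
    complication_subtypes: frozenset[str] = frozenset()


def flag_iron_and_fat(
    pancreas: PancreasMeasurement | None,
    liver: LiverMeasurement | None,
    heart: CardiacT2StarMap | None,
    ff_upper_limit_pct: float = FF_UPPER_LIMIT_PCT,
    pancreas_t2s_normal_ms: float = PANCREAS_T2S_NORMAL_MS,
    lic_significant_mg_g: float = LIC_SIGNIFICANT_MG_G,
    heart_t2s_normal_ms: float = HEART_T2S_NORMAL_MS,
) -> DiagnosticFlags:
    """Organ iron/fat flags from the aggregated organ measurements.

    Pancreatic iron overload: global T2* strictly below 26 ms.  Fatty
    replacement: global FF strictly above the normative limit (default
    6.6%, always injectable).  Significant hepatic iron: LIC >= 3 mg/g
    dw.  Significant myocardial iron: global heart T2* <= 20 ms.  A
    missing organ measurement leaves the corresponding flags unknown.
    """
    return DiagnosticFlags(
        pancreatic_iron_overload=(
            None if pancreas is None else pancreas.global_t2star_ms < pancreas_t2s_normal_ms
        ),
        pancreatic_fatty_replacement=(
            None if pancreas is None else pancreas.global_ff_pct > ff_upper_limit_pct
        ),
        significant_hepatic_iron=(
            None if liver is None else liver.lic_mg_g_dw >= lic_significant_mg_g
        ),
        significant_mio=(
            None if heart is None else heart.global_t2star_ms <= heart_t2s_normal_ms
        ),
        n_pathological_segments=(None if heart is None else heart.n_pathological_segments),
    )


@dataclass
class PatientRecord:
    """One subject's demographic, metabolic and MRI-derived fields.

    Mirrors the cohort column dictionary; any field other than ``id`` may
    be missing.  ``myocardial_fibrosis`` is tri-state ("present" /
    "absent" / "not_assessed") and is never coerced to a boolean.
    """

    id: str
    sex: str | None = None
    age_yr: float | None = None
    bmi_kg_m2: float | None = None
    splenectomy: bool | None = None
    hcv_status: str | None = None  # negative | eradicated | chronic
    ferritin_ng_ml: float | None = None
    hemoglobin_g_dl: float | None = None
    fpg_mg_dl: float | None = None
    glucose_1h_mg_dl: float | None = None
    glucose_2h_mg_dl: float | None = None
    insulin_uu_ml: float | None = None
    known_diabetes: bool | None = None
    pancreas: PancreasMeasurement | None = None
    liver: LiverMeasurement | None = None
    heart: CardiacT2StarMap | None = None
    lvef_pct: float | None = None
    rvef_pct: float | None = None
    edvi_ml_m2: float | None = None
    esvi_ml_m2: float | None = None
    myocardial_fibrosis: str | None = None
    jet_velocity_m_s: float | None = None
    heart_failure: bool | None = None
    arrhythmia: bool | None = None
    arrhythmia_subtype: str | None = None
    metabolic: MetabolicCriteria = field(default_factory=MetabolicCriteria)

    def diagnostic_flags(self, ff_upper_limit_pct: float = FF_UPPER_LIMIT_PCT) -> DiagnosticFlags:
        base = flag_iron_and_fat(
            self.pancreas, self.liver, self.heart, ff_upper_limit_pct=ff_upper_limit_pct
        )
        glucose = (
            classify_glucose(self.fpg_mg_dl, self.glucose_2h_mg_dl, bool(self.known_diabetes))
            if self.fpg_mg_dl is not None
            else None
        )
        comp, subtypes = classify_cardiac_complication(
            self.heart_failure, self.arrhythmia, self.jet_velocity_m_s
        )
        return DiagnosticFlags(
            pancreatic_iron_overload=base.pancreatic_iron_overload,
            pancreatic_fatty_replacement=base.pancreatic_fatty_replacement,
            significant_hepatic_iron=base.significant_hepatic_iron,
            significant_mio=base.significant_mio,
            n_pathological_segments=base.n_pathological_segments,
            glucose_class=glucose,
            metabolic_syndrome=classify_metabolic_syndrome(self.metabolic),
            cardiac_complication=comp,
            complication_subtypes=subtypes,
        )
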