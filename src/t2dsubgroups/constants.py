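"""Shared vocabulary for the subgrouping analysis.

Subgroup names follow the RHAPSODY lineage of data-driven type 2 diabetes
clusters: severe insulin-deficient (SIDD), severe insulin-resistant (SIRD),
mild obesity-related (MOD), mild (MD) and mild with high HDL-cholesterol
(MDH).
"""

# Canonical subgroup order; also the deterministic tie-break order for
# nearest-centre assignment.
SUBGROUPS = ("SIDD", "SIRD", "MOD", "MD", "MDH")

SEVERE_SUBGROUPS = frozenset({"SIDD", "SIRD"})
MILD_SUBGROUPS = frozenset({"MOD", "MD", "MDH"})

# The five clustering indicators, in the fixed component order used for all
# scaled vectors: age at the baseline observation (years), BMI (kg/m^2),
# HbA1c (mmol/mol), C-peptide (nmol/l), HDL-cholesterol (mmol/l).
INDICATORS = ("age", "bmi", "hba1c", "c_peptide", "hdl")

# Measurement columns carried on visits (units in the visits table schema).
MEASUREMENTS = (
    "bmi",
    "hba1c",
    "hdl",
    "c_peptide",
    "sbp",
    "dbp",
    "creatinine",
    "triglycerides",
    "total_chol",
    "ldl",
)

# The nine clinical parameters whose trajectories are modelled (C-peptide is
# excluded: it is assumed constant over follow-up).
TRAJECTORY_PARAMETERS = (
    "bmi",
    "hba1c",
    "hdl",
    "sbp",
    "dbp",
    "creatinine",
    "triglycerides",
    "total_chol",
    "ldl",
)

OUTCOMES = ("AMI", "CHF", "PVD", "stroke", "CKD", "ESRD")

TREATMENT_STEPS = ("NoTreatment", "OnlyCVD", "Step1", "Step2", "Step3", "OtherOAD")

SEXES = ("M", "F")
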