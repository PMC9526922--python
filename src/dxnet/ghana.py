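"""Ghana exemplar instance.

A condensed transcription of the published Ghana diagnostic-network
exemplar: the three-tier system (Primary health centers, Secondary
district hospitals, Tertiary referral hospitals), the top-20
burden-of-disease condition list plus antenatal care, the care-tier
logic (triage at Primary for most conditions, uncomplicated management
at Secondary except cancers at Tertiary, complicated management at
Tertiary), the published equipment-by-tier breakdown, and the published
capital prices: Primary $2,330 laboratory + $6,000 point-of-care
ultrasound; Secondary $296,000–$377,000 laboratory analyzers +
$275,000–$400,000 for one ultrasound and an X-ray machine.

The full national catalogue behind the published network (~111
diagnostics with their complete condition, medicine and format
mappings) is not redistributable here; this fixture instead carries a
representative ~45-diagnostic subset sufficient to exercise every
placement branch (on-site, send-out, patient referral), every
discipline, and the exact tier capital-cost arithmetic. Per-item price
splits within a tier are illustrative allocations; only the tier totals
are published figures.
"""

from __future__ import annotations

from .model import (
    CareAssignment,
    Condition,
    ConditionLevel,
    CostInterval,
    Diagnostic,
    DiagnosticIndication,
    EquipmentItem,
    Format,
    Medicine,
    MedicineAssignment,
    ModelInstance,
    Tier,
)

PRIMARY, SECONDARY, TERTIARY = "primary", "secondary", "tertiary"

_TIERS = (
    (PRIMARY, "Primary", 1),
    (SECONDARY, "Secondary", 2),
    (TERTIARY, "Tertiary", 3),
)

# (id, name, gbd_term)
_CONDITIONS = (
    ("acute_coronary_syndrome", "Acute coronary syndrome", "Ischemic heart disease"),
    ("antenatal_care", "Antenatal care", "Neonatal preterm birth; neonatal encephalopathy"),
    ("breast_cancer", "Breast cancer", None),
    ("cerebrovascular_disease", "Cerebrovascular disease", None),
    ("chronic_kidney_disease", "Chronic kidney disease", None),
    ("colorectal_cancer", "Colorectal cancer", None),
    ("copd", "COPD", None),
    ("dementia", "Dementia", "Alzheimer's disease (and related dementias)"),
    ("diabetes", "Diabetes", None),
    ("diarrhea", "Diarrhea, acute invasive bacterial", "Diarrheal diseases"),
    ("hiv", "HIV", None),
    ("hypertensive_heart_disease", "Hypertensive heart disease", None),
    ("liver_cancer", "Liver cancer", None),
    ("lung_cancer", "Lung cancer", "Tracheal, bronchus & lung cancer"),
    ("malaria", "Malaria", None),
    ("pneumonia", "Pneumonia, severe", "Lower respiratory infection"),
    ("preeclampsia", "Preeclampsia, HELLP", None),
    ("trauma", "Trauma", "Falls; interpersonal violence; road injuries; self-harm"),
    ("tuberculosis", "Tuberculosis", None),
)

_CANCERS = {"breast_cancer", "colorectal_cancer", "liver_cancer", "lung_cancer"}

# care-tier logic: triage at Primary (acute coronary syndrome: Secondary and
# above only); uncomplicated at Secondary, except cancers (Tertiary) and
# antenatal care / malaria (deliverable at Primary); complicated at Tertiary.
def _care_tier(condition_id: str, level: str) -> str:
    if level == "triage":
        return SECONDARY if condition_id == "acute_coronary_syndrome" else PRIMARY
    if level == "uncomplicated":
        if condition_id in _CANCERS:
            return TERTIARY
        if condition_id in ("antenatal_care", "malaria"):
            return PRIMARY
        return SECONDARY
    return TERTIARY


# (id, name, condition_id, level, eml_note)
_MEDICINES = (
    ("amoxicillin", "Amoxicillin", "pneumonia", "uncomplicated", None),
    ("ceftriaxone", "Ceftriaxone", "pneumonia", "complicated", None),
    ("gentamicin", "Gentamicin", "pneumonia", "complicated", None),
    ("artemether_lumefantrine", "Artemether-lumefantrine", "malaria", "uncomplicated", None),
    ("primaquine", "Primaquine", "malaria", "uncomplicated", None),
    ("metformin", "Metformin", "diabetes", "uncomplicated", None),
    ("arv_regimen", "Antiretroviral therapy (first-line)", "hiv", "uncomplicated", None),
    ("anti_tb_regimen", "First-line anti-tuberculosis regimen", "tuberculosis", "uncomplicated", None),
    ("sorafenib", "Sorafenib", "liver_cancer", "uncomplicated", "added beyond EML v20"),
    ("gefitinib", "Gefitinib", "lung_cancer", "uncomplicated", "added; on EML v21"),
)

# (id, name, cost_low, cost_high) — grouped by the tier whose rollup they
# belong to in the published equipment table; per-item splits within a tier
# are illustrative, tier sums are the published figures.
_EQUIPMENT = (
    # Primary: laboratory items sum to $2,330; POC ultrasound $6,000
    ("rdt_kits", "Rapid diagnostic test kits & dipsticks", 130, 130),
    ("glucometer", "Glucometer", 150, 150),
    ("hemoglobinometer", "Hemoglobinometer", 250, 250),
    ("basic_microscopy", "Microscope, basic (malaria, stool, urinalysis)", 1800, 1800),
    ("poc_ultrasound_unit", "Portable point-of-care ultrasound", 6000, 6000),
    # Secondary: laboratory analyzers sum to [296000, 377000]
    ("chemistry_analyzer", "Automated chemistry analyzer", 60000, 80000),
    ("immunoassay_analyzer", "Automated immunoassay analyzer", 70000, 90000),
    ("hematology_analyzer", "Automated hematology analyzer", 45000, 55000),
    ("coagulation_analyzer", "Automated coagulation analyzer", 25000, 35000),
    ("elisa_workstation", "ELISA workstation", 10000, 15000),
    ("benchtop_blood_gas", "Benchtop blood gas analyzer", 20000, 25000),
    ("benchtop_naat", "Benchtop nucleic acid amplification analyzer", 30000, 35000),
    ("stain_microscopy", "Microscopy with stains (Gram, AFB, trichrome, India ink)", 16000, 17000),
    ("bacterial_culture_lab", "Bacterial culture, identification & susceptibility", 20000, 25000),
    # Secondary: imaging sums to [275000, 400000]
    ("ultrasound_machine", "Ultrasound machine", 75000, 100000),
    ("xray_machine", "X-ray machine", 200000, 300000),
    # Tertiary: capital costs not validated; intervals are rough market
    # placeholders (reports label this tier's cost row accordingly).
    ("automated_naat", "Automated nucleic acid analyzer", 120000, 180000),
    ("hplc", "High-performance liquid chromatography", 40000, 80000),
    ("fluorescent_spot", "Fluorescent spot test setup (G6PD)", 2000, 5000),
    ("if_microscope", "Immunofluorescence microscope", 15000, 30000),
    ("transfusion_lab", "Transfusion testing laboratory", 25000, 50000),
    ("flow_cytometer", "Flow cytometer", 60000, 120000),
    ("histopathology_lab", "Histopathology laboratory", 80000, 150000),
    ("ihc_lab", "Immunohistochemistry setup", 30000, 60000),
    ("tb_fungal_culture", "Fungal & mycobacterial culture", 40000, 80000),
    ("ct_scanner", "Computed tomography scanner", 300000, 1000000),
    ("fluoroscopy_unit", "Fluoroscopy unit", 150000, 400000),
    ("echocardiograph", "Echocardiography system", 50000, 150000),
    ("mammography_unit", "Mammography unit", 100000, 250000),
    ("mri_scanner", "MRI scanner", 800000, 2000000),
)

# diagnostic: (id, name, discipline, modality,
#              formats: ((fmt_id, fmt_name, min_tier, equipment_ids), ...),
#              indications: (("c", condition, level, class) | ("m", medicine, class), ...))
_DIAGNOSTICS = (
    # --- performed at Primary -------------------------------------------
    ("hiv_serology", "HIV serology", "microbiology", "laboratory",
     (("hiv_rdt", "rapid diagnostic test", PRIMARY, ("rdt_kits",)),
      ("hiv_immunoassay", "automated immunoassay analyzer", SECONDARY, ("immunoassay_analyzer",)),
      ("hiv_elisa", "ELISA", SECONDARY, ("elisa_workstation",))),
     (("c", "hiv", "triage", "diagnosis"),
      ("c", "hiv", "uncomplicated", "diagnosis"))),
    ("malaria_parasite", "Malaria parasite detection", "microbiology", "laboratory",
     (("malaria_rdt", "rapid diagnostic test", PRIMARY, ("rdt_kits",)),
      ("malaria_microscopy", "thick & thin film microscopy", PRIMARY, ("basic_microscopy",))),
     (("c", "malaria", "triage", "diagnosis"),
      ("c", "malaria", "uncomplicated", "monitoring"))),
    ("glucose", "Glucose", "chemistry", "laboratory",
     (("glucose_meter", "glucometer", PRIMARY, ("glucometer",)),
      ("glucose_analyzer", "automated chemistry analyzer", SECONDARY, ("chemistry_analyzer",))),
     (("c", "diabetes", "triage", "diagnosis"),
      ("c", "diabetes", "uncomplicated", "monitoring"),
      ("c", "preeclampsia", "triage", "comorbidity"))),
    ("hemoglobin", "Hemoglobin", "hematology", "laboratory",
     (("hb_meter", "hemoglobinometer", PRIMARY, ("hemoglobinometer",)),),
     (("c", "antenatal_care", "uncomplicated", "monitoring"),
      ("c", "malaria", "uncomplicated", "comorbidity"))),
    ("urinalysis", "Urinalysis dipstick", "chemistry", "laboratory",
     (("urine_dipstick", "dipstick", PRIMARY, ("rdt_kits",)),),
     (("c", "preeclampsia", "triage", "diagnosis"),
      ("c", "chronic_kidney_disease", "triage", "diagnosis"))),
    ("urine_microscopy", "Urine microscopy", "microbiology", "laboratory",
     (("urine_micro", "microscopy", PRIMARY, ("basic_microscopy",)),),
     (("c", "chronic_kidney_disease", "triage", "diagnosis"),)),
    ("stool_microscopy", "Stool parasite microscopy", "microbiology", "laboratory",
     (("stool_micro", "microscopy", PRIMARY, ("basic_microscopy",)),),
     (("c", "diarrhea", "triage", "diagnosis"),)),
    ("fecal_occult_blood", "Fecal occult blood", "chemistry", "laboratory",
     (("fobt_card", "rapid immunochemical card", PRIMARY, ("rdt_kits",)),),
     (("c", "colorectal_cancer", "triage", "diagnosis"),)),
    ("pregnancy_test", "Urine hCG pregnancy test", "chemistry", "laboratory",
     (("hcg_strip", "rapid test strip", PRIMARY, ("rdt_kits",)),),
     (("c", "antenatal_care", "triage", "diagnosis"),)),
    ("g6pd", "G6PD activity", "chemistry", "laboratory",
     (("g6pd_rdt", "rapid diagnostic test", PRIMARY, ("rdt_kits",)),
      ("g6pd_spot", "fluorescent spot test", TERTIARY, ("fluorescent_spot",))),
     (("m", "primaquine", "toxicity"),)),
    ("poc_ultrasound", "Ultrasound, point-of-care (obstetric)", "radiology", "imaging",
     (("poc_us", "portable ultrasound", PRIMARY, ("poc_ultrasound_unit",)),),
     (("c", "antenatal_care", "uncomplicated", "monitoring"),)),
    # --- desired at Primary, infrastructure at Secondary (send-outs / referral)
    ("hba1c", "Hemoglobin A1c", "chemistry", "laboratory",
     (("hba1c_analyzer", "automated chemistry analyzer", SECONDARY, ("chemistry_analyzer",)),
      ("hba1c_hplc", "HPLC", TERTIARY, ("hplc",))),
     (("c", "diabetes", "triage", "diagnosis"),
      ("c", "diabetes", "uncomplicated", "monitoring"))),
    ("cbc", "Complete blood count", "hematology", "laboratory",
     (("cbc_analyzer", "automated hematology analyzer", SECONDARY, ("hematology_analyzer",)),),
     (("c", "antenatal_care", "uncomplicated", "comorbidity"),
      ("c", "malaria", "uncomplicated", "comorbidity"),
      ("c", "pneumonia", "uncomplicated", "diagnosis"))),
    ("lipid_panel", "Lipid panel", "chemistry", "laboratory",
     (("lipid_analyzer", "automated chemistry analyzer", SECONDARY, ("chemistry_analyzer",)),),
     (("c", "cerebrovascular_disease", "triage", "comorbidity"),
      ("c", "acute_coronary_syndrome", "uncomplicated", "monitoring"))),
    ("liver_function", "Liver function panel", "chemistry", "laboratory",
     (("lft_analyzer", "automated chemistry analyzer", SECONDARY, ("chemistry_analyzer",)),),
     (("c", "preeclampsia", "triage", "diagnosis"),
      ("c", "liver_cancer", "uncomplicated", "monitoring"),
      ("m", "sorafenib", "toxicity"))),
    ("renal_function", "Creatinine & urea (renal function)", "chemistry", "laboratory",
     (("renal_analyzer", "automated chemistry analyzer", SECONDARY, ("chemistry_analyzer",)),),
     (("c", "chronic_kidney_disease", "triage", "diagnosis"),
      ("c", "hypertensive_heart_disease", "uncomplicated", "comorbidity"),
      ("m", "gentamicin", "dose_adjustment"))),
    ("pancreatic_enzymes", "Lipase & amylase", "chemistry", "laboratory",
     (("lipase_analyzer", "automated chemistry analyzer", SECONDARY, ("chemistry_analyzer",)),),
     (("c", "trauma", "triage", "diagnosis"),)),
    ("blood_typing", "Blood grouping (ABO/RhD)", "transfusion", "laboratory",
     (("abo_manual", "manual tube typing", SECONDARY, ()),),
     (("c", "antenatal_care", "uncomplicated", "monitoring"),)),
    ("tb_naat", "TB nucleic acid amplification", "microbiology", "laboratory",
     (("tb_naat_benchtop", "benchtop NAAT analyzer", SECONDARY, ("benchtop_naat",)),
      ("tb_naat_automated", "automated nucleic acid analyzer", TERTIARY, ("automated_naat",))),
     (("c", "tuberculosis", "triage", "diagnosis"),)),
    ("xray", "X-ray (radiography)", "radiology", "imaging",
     (("xray_fixed", "fixed radiography unit", SECONDARY, ("xray_machine",)),),
     (("c", "pneumonia", "triage", "diagnosis"),
      ("c", "tuberculosis", "triage", "diagnosis"),
      ("c", "trauma", "uncomplicated", "diagnosis"))),
    # --- performed at Secondary ------------------------------------------
    ("pt_ptt", "Prothrombin time / PTT", "coagulation", "laboratory",
     (("coag_analyzer", "automated coagulation analyzer", SECONDARY, ("coagulation_analyzer",)),),
     (("c", "cerebrovascular_disease", "uncomplicated", "diagnosis"),
      ("c", "preeclampsia", "uncomplicated", "diagnosis"))),
    ("d_dimer", "D-dimer", "coagulation", "laboratory",
     (("ddimer_analyzer", "automated coagulation analyzer", SECONDARY, ("coagulation_analyzer",)),),
     (("c", "cerebrovascular_disease", "uncomplicated", "diagnosis"),)),
    ("cardiac_troponin", "Cardiac troponin", "chemistry", "laboratory",
     (("troponin_elisa", "ELISA", SECONDARY, ("elisa_workstation",)),),
     (("c", "acute_coronary_syndrome", "triage", "diagnosis"),)),
    ("bnp", "B-type natriuretic peptide", "chemistry", "laboratory",
     (("bnp_immunoassay", "automated immunoassay analyzer", SECONDARY, ("immunoassay_analyzer",)),),
     (("c", "hypertensive_heart_disease", "uncomplicated", "diagnosis"),)),
    ("bacterial_culture", "Bacterial culture & susceptibility", "microbiology", "laboratory",
     (("culture_lab", "culture with ID & AST", SECONDARY, ("bacterial_culture_lab",)),),
     (("c", "pneumonia", "uncomplicated", "diagnosis"),
      ("c", "diarrhea", "uncomplicated", "diagnosis"))),
    ("gram_stain", "Gram stain microscopy", "microbiology", "laboratory",
     (("gram_micro", "stained microscopy", SECONDARY, ("stain_microscopy",)),),
     (("c", "pneumonia", "uncomplicated", "diagnosis"),)),
    ("afb_smear", "AFB smear microscopy", "microbiology", "laboratory",
     (("afb_micro", "stained microscopy", SECONDARY, ("stain_microscopy",)),),
     (("c", "tuberculosis", "uncomplicated", "monitoring"),)),
    ("blood_gas", "Blood gas analysis", "chemistry", "laboratory",
     (("bga_benchtop", "benchtop blood gas analyzer", SECONDARY, ("benchtop_blood_gas",)),),
     (("c", "copd", "uncomplicated", "monitoring"),
      ("c", "pneumonia", "uncomplicated", "diagnosis"))),
    ("electrolytes", "Serum electrolytes", "chemistry", "laboratory",
     (("lyte_analyzer", "automated chemistry analyzer", SECONDARY, ("chemistry_analyzer",)),),
     (("c", "chronic_kidney_disease", "uncomplicated", "monitoring"),
      ("c", "diarrhea", "uncomplicated", "diagnosis"))),
    ("ultrasound", "Ultrasound (diagnostic)", "radiology", "imaging",
     (("us_fixed", "ultrasound machine", SECONDARY, ("ultrasound_machine",)),),
     (("c", "trauma", "uncomplicated", "diagnosis"),
      ("c", "liver_cancer", "uncomplicated", "monitoring"))),
    # --- performed at Tertiary -------------------------------------------
    ("ct_scan", "Computed tomography", "radiology", "imaging",
     (("ct_unit", "CT scanner", TERTIARY, ("ct_scanner",)),),
     (("c", "cerebrovascular_disease", "complicated", "diagnosis"),
      ("c", "trauma", "complicated", "diagnosis"))),
    ("fluoroscopy", "Fluoroscopy", "radiology", "imaging",
     (("fluoro_unit", "fluoroscopy unit", TERTIARY, ("fluoroscopy_unit",)),),
     (("c", "colorectal_cancer", "uncomplicated", "diagnosis"),)),
    ("echocardiogram", "Echocardiogram", "radiology", "imaging",
     (("echo_unit", "echocardiography system", TERTIARY, ("echocardiograph",)),),
     (("c", "hypertensive_heart_disease", "complicated", "diagnosis"),
      ("c", "acute_coronary_syndrome", "complicated", "monitoring"))),
    ("mri", "Magnetic resonance imaging", "radiology", "imaging",
     (("mri_unit", "MRI scanner", TERTIARY, ("mri_scanner",)),),
     (("c", "cerebrovascular_disease", "complicated", "diagnosis"),
      ("c", "dementia", "complicated", "diagnosis"))),
    ("mammography", "Mammography", "radiology", "imaging",
     (("mammo_unit", "mammography unit", TERTIARY, ("mammography_unit",)),),
     (("c", "breast_cancer", "uncomplicated", "diagnosis"),)),
    ("histopathology", "Histopathology (biopsy)", "anatomic pathology", "laboratory",
     (("histo_lab", "histopathology laboratory", TERTIARY, ("histopathology_lab",)),),
     (("c", "breast_cancer", "uncomplicated", "diagnosis"),
      ("c", "colorectal_cancer", "uncomplicated", "diagnosis"),
      ("c", "liver_cancer", "uncomplicated", "diagnosis"),
      ("c", "lung_cancer", "uncomplicated", "diagnosis"))),
    ("immunohistochemistry", "Immunohistochemistry (ER/PR/HER2)", "anatomic pathology", "laboratory",
     (("ihc_bench", "immunohistochemistry", TERTIARY, ("ihc_lab",)),),
     (("c", "breast_cancer", "uncomplicated", "diagnosis"),)),
    ("egfr_mutation", "EGFR mutation testing", "molecular", "laboratory",
     (("egfr_naat", "automated nucleic acid analyzer", TERTIARY, ("automated_naat",)),),
     (("m", "gefitinib", "companion"),)),
    ("afp", "Alpha-fetoprotein", "chemistry", "laboratory",
     (("afp_immunoassay", "automated immunoassay analyzer", SECONDARY, ("immunoassay_analyzer",)),),
     (("c", "liver_cancer", "uncomplicated", "diagnosis"),
      ("c", "liver_cancer", "complicated", "monitoring"))),
    ("drug_levels", "Therapeutic drug monitoring (aminoglycosides)", "toxicology", "laboratory",
     (("tdm_hplc", "HPLC", TERTIARY, ("hplc",)),),
     (("m", "gentamicin", "toxicity"),)),
    ("cd4_count", "CD4+ T-cell count", "flow cytometry", "laboratory",
     (("cd4_flow", "flow cytometry", TERTIARY, ("flow_cytometer",)),),
     (("c", "hiv", "complicated", "monitoring"),)),
    ("crossmatch", "Blood crossmatch & antibody screen", "transfusion", "laboratory",
     (("xm_lab", "transfusion laboratory", TERTIARY, ("transfusion_lab",)),),
     (("c", "trauma", "complicated", "diagnosis"),
      ("c", "preeclampsia", "complicated", "diagnosis"))),
    ("hiv_viral_load", "HIV viral load", "molecular", "laboratory",
     (("vl_naat", "automated nucleic acid analyzer", TERTIARY, ("automated_naat",)),),
     (("c", "hiv", "uncomplicated", "monitoring"),)),
    ("mycobacterial_culture", "Fungal & mycobacterial culture", "microbiology", "laboratory",
     (("tb_culture_lab", "culture laboratory", TERTIARY, ("tb_fungal_culture",)),),
     (("c", "tuberculosis", "complicated", "diagnosis"),)),
    ("immunofluorescence", "Autoimmune serology (immunofluorescence)", "immunology", "laboratory",
     (("if_bench", "immunofluorescence microscopy", TERTIARY, ("if_microscope",)),),
     (("c", "chronic_kidney_disease", "complicated", "diagnosis"),)),
)

_LEVEL_DEFS = {
    "triage": "identify suspected cases and refer for diagnosis and management",
    "uncomplicated": "management of the uncomplicated condition",
    "complicated": "management of the condition with complications",
}


def ghana_fixture() -> ModelInstance:
    """Build the Ghana exemplar instance (always passes validation)."""
    tiers = tuple(Tier(id=i, name=n, rank=r) for i, n, r in _TIERS)
    conditions = tuple(
        Condition(id=i, name=n, gbd_term=g, source_lists=("GBD-20",) if i != "antenatal_care" else ("added",))
        for i, n, g in _CONDITIONS
    )
    condition_levels = tuple(
        ConditionLevel(condition_id=c.id, level=lvl, definition=_LEVEL_DEFS[lvl])
        for c in conditions
        for lvl in ("triage", "uncomplicated", "complicated")
    )
    care = tuple(
        CareAssignment(condition_id=cl.condition_id, level=cl.level, tier_id=_care_tier(cl.condition_id, cl.level))
        for cl in condition_levels
    )
    medicines = tuple(
        Medicine(id=i, name=n, eml_note=note) for i, n, _, _, note in _MEDICINES
    )
    med_assignments = tuple(
        MedicineAssignment(medicine_id=i, condition_id=c, level=lvl)
        for i, _, c, lvl, _ in _MEDICINES
    )
    equipment = tuple(
        EquipmentItem(id=i, name=n, cost=CostInterval(low=lo, high=hi))
        for i, n, lo, hi in _EQUIPMENT
    )

    diagnostics, formats, indications = [], [], []
    for d_id, name, discipline, modality, fmts, inds in _DIAGNOSTICS:
        diagnostics.append(
            Diagnostic(id=d_id, name=name, discipline=discipline, modality=modality)
        )
        for f_id, f_name, min_tier, eq in fmts:
            formats.append(
                Format(id=f_id, diagnostic_id=d_id, name=f_name, min_tier_id=min_tier, equipment_ids=eq)
            )
        for ind in inds:
            if ind[0] == "c":
                _, cond, lvl, cls = ind
                indications.append(
                    DiagnosticIndication(
                        diagnostic_id=d_id, condition_id=cond, level=lvl, indication_class=cls
                    )
                )
            else:
                _, med, cls = ind
                indications.append(
                    DiagnosticIndication(diagnostic_id=d_id, medicine_id=med, indication_class=cls)
                )

    return ModelInstance(
        tiers=tiers,
        conditions=conditions,
        condition_levels=condition_levels,
        care_assignments=care,
        medicines=medicines,
        medicine_assignments=med_assignments,
        diagnostics=tuple(diagnostics),
        indications=tuple(indications),
        formats=tuple(formats),
        equipment=equipment,
    )
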