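# Column mapping for the deposited 48-patient study table (S1 Dataset).
#
# The table itself cannot be redistributed with this package; download it
# from the journal's supplementary material, place it next to this file as
# data/s1_dataset.xlsx (or .csv), copy this template to
# data/s1_schema_map.yaml and replace every right-hand side with the
# actual column header used in the spreadsheet.
#
# Clinical columns (canonical name: source column header)
patient_id: "REPLACE: patient identifier column"
age: "REPLACE: age (years)"
sex: "REPLACE: sex"
smoking_status: "REPLACE: smoking status"
extrathoracic_metastasis: "REPLACE: extrathoracic metastasis yes/no"
egfr_mutation: "REPLACE: EGFR mutation subtype"
baseline_diameter: "REPLACE: baseline tumour diameter (mm)"
followup_diameter: "REPLACE: follow-up tumour diameter (mm)"
recist_response: "REPLACE: RECIST response (responder/nonresponder)"
pfs_months: "REPLACE: progression-free survival (months)"
event: "REPLACE: progression/death observed flag"
# Radiomic feature columns use "<set>:<canonical feature name>" keys,
# where <set> is baseline, followup or percent_change and the canonical
# feature names are those in radsurv.features.FEATURE_NAMES, e.g.:
#
# "baseline:roundness": "Roundness"
# "followup:roundness": "Roundness_FU"
# "followup:grey-level nonuniformity": "GLN_FU"
# "percent_change:volume": "Volume_change"
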