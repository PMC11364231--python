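# SYNTHETIC default fee schedule (TZS). Placeholder prices for self-contained
# runs and tests only -- NOT the hospital's real price list. Supply actual
# prices via --schedule for any real analysis.
code,category,unit_cost_tzs,modality,variant,ward
consult_em,consult_specialist,25000,,,
consult_surgery,consult_specialist,30000,,,
consult_cardiology,consult_specialist,30000,,,
consult_psychiatry,consult_specialist,28000,,,
consult_urology,consult_specialist,30000,,,
consult_dentist,consult_generalist,15000,,,
consult_gp,consult_generalist,12000,,,
consult_physio,consult_therapy,10000,,,
proc_intubation,procedure_nonsurgical,60000,,,
proc_npa,procedure_nonsurgical,15000,,,
proc_oxygen,procedure_nonsurgical,25000,,,
proc_fluids,procedure_nonsurgical,12000,,,
proc_transfusion,procedure_nonsurgical,55000,,,
surg_debridement_exfix,procedure_surgical,360000,,,
surg_orif,procedure_surgical,450000,,,
surg_laparotomy,procedure_surgical,400000,,,
surg_craniotomy,procedure_surgical,520000,,,
surg_tracheostomy,procedure_surgical,280000,,,
img_xray_uni,imaging,18000,xray,unilateral,
img_xray_bil,imaging,30000,xray,bilateral,
img_ct_head,imaging,210000,ct,head,
img_ct_body,imaging,260000,ct,body,
img_mri_head,imaging,350000,mri,head,
img_mri_spine,imaging,420000,mri,spine,
img_uss_abdomen,imaging,35000,uss,abdomen,
img_uss_fast,imaging,30000,uss,fast,
adm_general,admission_day,22000,,,general
adm_icu,admission_day,160000,,,icu
cons_saline,consumable,8000,,,
cons_blood_unit,consumable,45000,,,
cons_dressing_kit,consumable,10000,,,
death_certificate,death_expense,20000,,,
death_morgue_transport,death_expense,12000,,,
death_body_bag,death_expense,15000,,,
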