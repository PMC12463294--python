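pt_name,soc
Hypoglycaemia,Metabolism and nutrition disorders
Shock hypoglycaemic,Metabolism and nutrition disorders
Hypoglycaemia unawareness,Metabolism and nutrition disorders
Insulin resistance,Metabolism and nutrition disorders
Ketoacidosis,Metabolism and nutrition disorders
Dawn phenomenon,Metabolism and nutrition disorders
Hyperinsulinaemic hypoglycaemia,Metabolism and nutrition disorders
Ketosis,Metabolism and nutrition disorders
Hypoglycaemia neonatal,Metabolism and nutrition disorders
Blood glucose abnormal,Investigations
Blood glucose fluctuation,Investigations
Blood glucose decreased,Investigations
Anti-insulin antibody positive,Investigations
Glycosylated haemoglobin decreased,Investigations
Blood ketone body,Investigations
Blood ketone body increased,Investigations
Blood insulin increased,Investigations
Blood ketone body present,Investigations
Injection site injury,General disorders and administration site conditions
Injection site hypertrophy,General disorders and administration site conditions
Injection site atrophy,General disorders and administration site conditions
Injection site scar,General disorders and administration site conditions
Injection site haemorrhage,General disorders and administration site conditions
Injection site discolouration,General disorders and administration site conditions
Injection site bruising,General disorders and administration site conditions
Injection site pain,General disorders and administration site conditions
Hunger,General disorders and administration site conditions
Cataract operation,Surgical and medical procedures
Eye operation,Surgical and medical procedures
Cardiac operation,Surgical and medical procedures
Eye laser surgery,Surgical and medical procedures
Vascular graft,Surgical and medical procedures
Coronary artery bypass,Surgical and medical procedures
Retinal operation,Surgical and medical procedures
Laser therapy,Surgical and medical procedures
Visual impairment,Eye disorders
Retinopathy,Eye disorders
Macular degeneration,Eye disorders
Cataract,Eye disorders
Eye haemorrhage,Eye disorders
Blindness,Eye disorders
Retinal disorder,Eye disorders
Retinopathy proliferative,Eye disorders
Blindness unilateral,Eye disorders
Eye disorder,Eye disorders
Visual acuity reduced,Eye disorders
Glaucoma,Eye disorders
Retinal haemorrhage,Eye disorders
Corrective lens user,Social circumstances
Disability,Social circumstances
Wheelchair user,Social circumstances
Hearing disability,Social circumstances
Hearing aid user,Social circumstances
Hypoglycaemic seizure,Nervous system disorders
Hypoglycaemic unconsciousness,Nervous system disorders
Hypoglycaemic coma,Nervous system disorders
Hypoglycaemic encephalopathy,Nervous system disorders
Dementia Alzheimer’s type,Nervous system disorders
Dementia,Nervous system disorders
Dyslexia,Nervous system disorders
Cerebrovascular accident,Nervous system disorders
Lipohypertrophy,Skin and subcutaneous tissue disorders
Cutaneous amyloidosis,Skin and subcutaneous tissue disorders
Lipodystrophy acquired,Skin and subcutaneous tissue disorders
Lack of injection site rotation,"Injury, poisoning and procedural complications"
Exposure via skin contact,"Injury, poisoning and procedural complications"
Pancreatic disorder,Other SOC
Frustration tolerance decreased,Other SOC
Hypoacusis,Other SOC
Neuropathic arthropathy,Other SOC
Decreased insulin requirement,Metabolism and nutrition disorders
Underweight,Metabolism and nutrition disorders
Exposure during pregnancy,"Injury, poisoning and procedural complications"
Hospitalisation,Surgical and medical procedures
Intensive care,Surgical and medical procedures
Kidney malformation,"Congenital, familial and genetic disorders"
Congenital bladder anomaly,"Congenital, familial and genetic disorders"
Gastrointestinal malformation,"Congenital, familial and genetic disorders"
Jaundice neonatal,"Pregnancy, puerperium and perinatal conditions"
Foetal distress syndrome,"Pregnancy, puerperium and perinatal conditions"
Abortion,"Pregnancy, puerperium and perinatal conditions"
Foetal disorder,"Pregnancy, puerperium and perinatal conditions"
Polyhydramnios,"Pregnancy, puerperium and perinatal conditions"
Foetal hypokinesia,"Pregnancy, puerperium and perinatal conditions"
Foetal macrosomia,"Pregnancy, puerperium and perinatal conditions"
Abnormal labour,"Pregnancy, puerperium and perinatal conditions"
Kidney infection,Infections and infestations
Respiratory arrest,"Respiratory, thoracic and mediastinal disorders"
Jaundice,Hepatobiliary disorders
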