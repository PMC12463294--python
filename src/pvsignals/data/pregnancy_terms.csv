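smq_code,pt_code,pt_name,role
,10071407,MATERNAL EXPOSURE DURING DELIVERY,pregnancy-inclusion
,10071409,FOETAL EXPOSURE DURING DELIVERY,pregnancy-inclusion
,10071406,MATERNAL EXPOSURE BEFORE PREGNANCY,pregnancy-inclusion
,10071408,MATERNAL EXPOSURE DURING PREGNANCY,pregnancy-inclusion
,10071404,FOETAL EXPOSURE DURING PREGNANCY,pregnancy-inclusion
,10073513,EXPOSURE DURING PREGNANCY,pregnancy-inclusion
,10071415,MATERNAL EXPOSURE TIMING UNSPECIFIED,pregnancy-inclusion
,10071405,FOETAL EXPOSURE TIMING UNSPECIFIED,pregnancy-inclusion
,10026923,MATERNAL DRUGS AFFECTING FOETUS,pregnancy-inclusion
,10064998,DRUG EXPOSURE BEFORE PREGNANCY,pregnancy-inclusion
,10050425,PATERNAL DRUGS AFFECTING FOETUS,pregnancy-inclusion
,10071403,EXPOSURE VIA FATHER,pregnancy-inclusion
,10080091,PATERNAL EXPOSURE DURING PREGNANCY,pregnancy-inclusion
,10080092,PATERNAL EXPOSURE TIMING UNSPECIFIED,pregnancy-inclusion
,10080093,PATERNAL EXPOSURE BEFORE PREGNANCY,pregnancy-inclusion
,10084938,MATERNAL EXPOSURE VIA PARTNER DURING PREGNANCY,pregnancy-inclusion
,10071409,FOETAL EXPOSURE DURING DELIVERY,fetal-neonatal
,10071404,FOETAL EXPOSURE DURING PREGNANCY,fetal-neonatal
,10071405,FOETAL EXPOSURE TIMING UNSPECIFIED,fetal-neonatal
,10026923,MATERNAL DRUGS AFFECTING FOETUS,fetal-neonatal
,,HYPOGLYCAEMIA NEONATAL,fetal-neonatal
,,JAUNDICE NEONATAL,fetal-neonatal
,,FOETAL DISTRESS SYNDROME,fetal-neonatal
,,GESTATIONAL DIABETES,indication-inclusion
,,PREGNANCY,indication-inclusion
,,DIABETES MELLITUS IN PREGNANCY,indication-inclusion
,,MATERNAL EXPOSURE DURING PREGNANCY,indication-inclusion
,10050425,PATERNAL DRUGS AFFECTING FOETUS,paternal-exposure
,10071403,EXPOSURE VIA FATHER,paternal-exposure
,10080091,PATERNAL EXPOSURE DURING PREGNANCY,paternal-exposure
,10080092,PATERNAL EXPOSURE TIMING UNSPECIFIED,paternal-exposure
,10080093,PATERNAL EXPOSURE BEFORE PREGNANCY,paternal-exposure
,10084938,MATERNAL EXPOSURE VIA PARTNER DURING PREGNANCY,paternal-exposure
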