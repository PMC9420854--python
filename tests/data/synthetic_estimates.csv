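study_id,predictor,endpoint_label,endpoint_class,measure,point,ci_lower,ci_upper,ci_level,scale,unit,sd_value,conversion_factor,adjusted
s01,TSH_CONTINUOUS,MACE composite,STUDY_MACE,HR,0.88,0.78,0.99,0.95,PER_LOG_UNIT,log mIU/L,,,true
s02,TSH_CONTINUOUS,MACE composite,STUDY_MACE,HR,0.95,0.9,1.01,0.95,PER_UNIT,mIU/L,,,true
s03,TSH_CONTINUOUS,MACE composite,STUDY_MACE,HR,1.04,0.97,1.12,0.95,PER_UNIT,mIU/L,,,true
s03,TSH_CONTINUOUS,MACE composite,STUDY_MACE,HR,1.09,1.01,1.18,0.95,PER_UNIT,mIU/L,,,false
s04,TSH_CONTINUOUS,MACE composite,STUDY_MACE,HR,0.91,0.82,1.01,0.95,PER_UNIT,mIU/L,,,true
s05,TSH_CONTINUOUS,MACE composite,STUDY_MACE,HR,0.85,0.7,1.03,0.95,PER_SD,mIU/L,1.8,,true
s06,TSH_CONTINUOUS,cardiovascular death,CVD,HR,0.9,0.81,1.0,0.95,PER_UNIT,mIU/L,,,true
s07,TSH_CONTINUOUS,cardiovascular death,CVD,HR,0.86,0.74,1.0,0.95,PER_UNIT,mIU/L,,,true
s08,TSH_CONTINUOUS,cardiovascular death,CVD,HR,0.82,0.66,1.02,0.95,PER_LOG_UNIT,log mIU/L,,,true
s09,TSH_CONTINUOUS,cardiovascular death,CVD,HR,0.93,0.83,1.04,0.95,PER_UNIT,mIU/L,,,false
s01,FT4_CONTINUOUS,MACE composite,STUDY_MACE,HR,1.3,1.05,1.61,0.95,PER_UNIT,ng/dL,,0.0777,true
s02,FT4_CONTINUOUS,MACE composite,STUDY_MACE,HR,1.45,1.12,1.88,0.95,PER_SD,pmol/L,2.3,,true
s10,FT4_CONTINUOUS,MACE composite,STUDY_MACE,HR,1.07,1.02,1.12,0.95,PER_UNIT,pmol/L,,,true
s11,FT4_CONTINUOUS,MACE composite,STUDY_MACE,HR,1.05,1.0,1.1,0.95,PER_UNIT,pmol/L,,,true
s12,FT4_CONTINUOUS,MACE composite,STUDY_MACE,HR,1.09,1.03,1.15,0.95,PER_UNIT,pmol/L,,,true
s10,FT4_CONTINUOUS,cardiovascular death,CVD,HR,1.06,1.0,1.12,0.95,PER_UNIT,pmol/L,,,true
s13,FT4_CONTINUOUS,cardiovascular death,CVD,HR,1.08,1.01,1.16,0.95,PER_UNIT,pmol/L,,,true
s14,FT4_CONTINUOUS,cardiovascular death,CVD,HR,1.04,0.98,1.11,0.95,PER_UNIT,pmol/L,,,true
s06,FT4_CONTINUOUS,sudden cardiac death,SCD,HR,1.11,1.03,1.2,0.95,PER_UNIT,pmol/L,,,true
s15,FT4_CONTINUOUS,sudden cardiac death,SCD,HR,1.16,1.04,1.29,0.95,PER_UNIT,pmol/L,,,true
s15,TSH_CONTINUOUS,sudden cardiac death,SCD,HR,0.95,0.83,1.09,0.95,PER_LOG_UNIT,log mIU/L,,,true
s16,SUBCLINICAL_HYPO,cardiovascular death,CVD,HR,1.18,1.02,1.37,0.95,CATEGORICAL,,,,true
s17,SUBCLINICAL_HYPO,cardiovascular death,CVD,OR,1.25,1.01,1.55,0.95,CATEGORICAL,,,,true
s18,SUBCLINICAL_HYPO,cardiovascular death,CVD,HR,1.12,0.95,1.32,0.95,CATEGORICAL,,,,true
s16,SUBCLINICAL_HYPER,cardiovascular death,CVD,HR,1.21,1.0,1.46,0.95,CATEGORICAL,,,,true
s17,SUBCLINICAL_HYPER,cardiovascular death,CVD,HR,1.15,0.92,1.44,0.95,CATEGORICAL,,,,true
s18,SUBCLINICAL_HYPER,MACE composite,STUDY_MACE,HR,1.1,0.96,1.26,0.95,CATEGORICAL,,,,true
s04,TSH_CONTINUOUS,all-cause mortality,ALL_CAUSE_MORTALITY,HR,0.97,0.91,1.03,0.95,PER_UNIT,mIU/L,,,true
s11,FT4_CONTINUOUS,appropriate ICD therapy,ICD_THERAPY,HR,1.14,1.01,1.29,0.95,PER_UNIT,pmol/L,,,true
s05,FT4_CONTINUOUS,MACE composite,STUDY_MACE,HR,1.12,1.01,1.24,0.95,PER_UNIT,pmol/L,,,true
s05,FT4_CONTINUOUS,MACE composite,STUDY_MACE,HR,1.15,1.03,1.28,0.95,PER_UNIT,pmol/L,,,true
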