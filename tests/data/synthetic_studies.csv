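study_id,first_author,year,design,n_subjects,followup_years,nos_score,is_human,is_longitudinal,reports_quantitative_thyroid,reports_hr_or_or,is_case_report,is_animal_or_cell,is_therapeutic_trial,is_nti_study,is_amiodarone_study,is_survey_or_review,duplicate_of
s01,Adler,2007,prospective,537,2.45,7,true,true,true,true,false,false,false,false,false,false,
s02,Berg,2014,prospective,674,2.9,8,true,true,true,true,false,false,false,false,false,false,
s03,Chen,2021,retrospective,811,3.35,9,true,true,true,true,false,false,false,false,false,false,
s04,Dvorak,2006,prospective,948,3.8,6,true,true,true,true,false,false,false,false,false,false,
s05,Evans,2013,prospective,1085,4.25,7,true,true,true,true,false,false,false,false,false,false,
s06,Fischer,2020,retrospective,1222,4.7,8,true,true,true,true,false,false,false,false,false,false,
s07,Garcia,2005,prospective,1359,5.15,9,true,true,true,true,false,false,false,false,false,false,
s08,Huang,2012,prospective,1496,5.6,6,true,true,true,true,false,false,false,false,false,false,
s09,Ito,2019,retrospective,1633,6.05,7,true,true,true,true,false,false,false,false,false,false,
s10,Jensen,2004,prospective,1770,6.5,8,true,true,true,true,false,false,false,false,false,false,
s11,Kim,2011,prospective,1907,6.95,9,true,true,true,true,false,false,false,false,false,false,
s12,Larsen,2018,retrospective,2044,7.4,6,true,true,true,true,false,false,false,false,false,false,
s13,Meyer,2003,prospective,2181,7.85,7,true,true,true,true,false,false,false,false,false,false,
s14,Novak,2010,prospective,2318,8.3,8,true,true,true,true,false,false,false,false,false,false,
s15,Olsen,2017,retrospective,2455,8.75,9,true,true,true,true,false,false,false,false,false,false,
s16,Petrov,2002,prospective,2592,9.2,6,true,true,true,true,false,false,false,false,false,false,
s17,Quint,2009,prospective,2729,9.65,7,true,true,true,true,false,false,false,false,false,false,
s18,Rossi,2016,retrospective,2866,10.1,8,true,true,true,true,false,false,false,false,false,false,
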