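study_id,disorder_id,subtype_id,costing_year,currency,cost_healthcare,cost_nonmedical,cost_indirect,basis,indirect_basis,quality_high,excluded_outlier
rovira2012,anxiety_disorders,generalized_anxiety_disorder,2006,EUR,1206,162,4451,prevalence,working_age,False,False
coduras2010,dementia,alzheimer,2006,EUR,4272,12708,,prevalence,working_age,True,False
lopez_bastida2006,dementia,alzheimer,2001,EUR,3289,24281,628,prevalence,working_age,True,False
lopez_pousa2004,dementia,alzheimer,2001,EUR,,,6649,prevalence,working_age,False,False
sicras2005,dementia,alzheimer,2003,EUR,5706,15444,,prevalence,working_age,False,False
turro_garriga2010,dementia,alzheimer,2006,EUR,8212,,,prevalence,working_age,False,False
gustavsson2011,dementia,alzheimer,2007,GBP,4189,18504,,prevalence,working_age,False,False
sicras2005,dementia,vascular,2003,EUR,6090,20034,,prevalence,working_age,False,False
oliva2007,dementia,alzheimer,2002,EUR,,11110,,prevalence,working_age,True,False
wimo2007,dementia,alzheimer,2005,USD,6219,14989,,prevalence,working_age,False,False
sancho2008,epilepsy,,2005,EUR,4982,255,1618,prevalence,working_age,True,False
villanueva2012,epilepsy,,2010,EUR,3843,951,,prevalence,working_age,True,False
badia2004,headache,migraine,2001,EUR,198,,54,prevalence,working_age,True,False
bloudek2012,headache,migraine,2010,EUR,1217,,,prevalence,working_age,False,False
linde2012,headache,migraine,2010,EUR,130,,257,prevalence,working_age,True,False
linde2012,headache,tension_type,2010,EUR,19,,26,prevalence,working_age,True,False
linde2012,headache,medication_overuse,2010,EUR,404,,873,prevalence,working_age,True,False
linde2012,headache,other,2010,EUR,22,,0,prevalence,working_age,True,False
salvador_carulla2011,mood_disorders,unipolar,2006,EUR,4002,,1346,prevalence,working_age,True,False
sicras_mainar2012,mood_disorders,unipolar,2009,EUR,620,,1275,prevalence,working_age,False,False
sicras_mainar2010,mood_disorders,unipolar,2006,EUR,1579,,1810,prevalence,working_age,False,False
serna2007,mood_disorders,unipolar,2004,EUR,335,,268,prevalence,working_age,False,False
gonzalez_pinto2010,mood_disorders,bipolar,2003,EUR,283,,,prevalence,working_age,False,False
kobelt2006,multiple_sclerosis,,2005,EUR,12142,12540,8145,prevalence,working_age,True,False
arroyo2011,multiple_sclerosis,,2009,EUR,9895,5510,,prevalence,working_age,False,False
casado2006,multiple_sclerosis,,2004,EUR,7775,21297,16618,prevalence,working_age,True,False
karampampa2012,multiple_sclerosis,,2009,EUR,15958,5235,7732,prevalence,working_age,True,False
cubo2009,parkinsons_disease,,2004,EUR,7380,3817,8235,prevalence,working_age,False,False
oliva2007,parkinsons_disease,,2002,EUR,,4255,,prevalence,working_age,True,False
olivares2008,psychotic_disorders,,2005,EUR,5569,,,prevalence,working_age,False,False
vazquez_polo2005,psychotic_disorders,,1999,EUR,3989,,,prevalence,working_age,False,False
beguiristain2005,stroke,,2002,EUR,5048,,,prevalence,working_age,True,False
hervas_angulo2006,stroke,,2004,EUR,2271,1863,426,prevalence,working_age,True,False
mar2011,stroke,,2008,EUR,16341,10932,,prevalence,working_age,False,True
sicras2008,stroke,,2006,EUR,1591,,,prevalence,working_age,False,False
oliva2007,stroke,,2002,EUR,,4478,,prevalence,working_age,False,False
hervas2007,stroke,,2004,EUR,,21551,,prevalence,working_age,False,True
navarrete_navarro2007,stroke,,2004,EUR,1425,5537,741,prevalence,working_age,True,False
hervas_angulo2006,stroke,,2004,EUR,4470,1289,572,incidence,working_age,True,False
navarrete_navarro2007,stroke,,2004,EUR,5173,6420,2347,incidence,working_age,True,False
lopez_bastida2009,neuromuscular_disorders,amyotrophic_lateral_sclerosis,2004,EUR,8018,19602,8575,prevalence,working_age,True,False
mar2011,traumatic_brain_injury,,2008,EUR,11109,8914,,prevalence,working_age,False,True
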