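disorder_id,n_patients,working_age_fraction
addiction,1437560,1.0
anxiety_disorders,6238499,1.0
brain_tumor,20695,1.0
child_adolescent_disorders,480074,1.0
dementia,608711,1.0
eating_disorders,131049,1.0
epilepsy,225346,1.0
headache,13909125,1.0
intellectual_disability,376777,1.0
mood_disorders,3002725,1.0
multiple_sclerosis,36193,1.0
neuromuscular_disorders,23003,1.0
parkinsons_disease,79789,1.0
personality_disorders,396532,1.0
psychotic_disorders,453650,1.0
sleep_disorders,4072265,1.0
somatoform_disorders,1852405,1.0
stroke,644025,1.0
traumatic_brain_injury,335260,1.0
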