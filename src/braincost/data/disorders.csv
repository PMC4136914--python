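disorder_id,group,indirect_forced_zero,subtype_weights
addiction,mental,False,
anxiety_disorders,mental,False,generalized_anxiety_disorder:0.1;other_anxiety:0.9
child_adolescent_disorders,mental,True,
eating_disorders,mental,False,
intellectual_disability,mental,False,
mood_disorders,mental,False,unipolar:0.81762;bipolar:0.18238
personality_disorders,mental,False,
psychotic_disorders,mental,False,
sleep_disorders,mental,False,
somatoform_disorders,mental,False,
brain_tumor,neurological,False,
dementia,neurological,True,
epilepsy,neurological,False,
headache,neurological,False,migraine:0.31894;tension_type:0.20698;medication_overuse:0.12665;other:0.34743
multiple_sclerosis,neurological,False,
neuromuscular_disorders,neurological,False,amyotrophic_lateral_sclerosis:0.1;other_neuromuscular:0.9
parkinsons_disease,neurological,False,
stroke,neurological,False,
traumatic_brain_injury,neurological,False,
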