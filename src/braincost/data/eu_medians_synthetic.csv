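disorder_id,subtype_id,category,amount_eur2010
addiction,,healthcare,1335.0
addiction,,nonmedical,867.0
addiction,,indirect,1315.0
brain_tumor,,healthcare,12428.0
brain_tumor,,indirect,6826.0
child_adolescent_disorders,,healthcare,392.0
child_adolescent_disorders,,nonmedical,3021.0
eating_disorders,,healthcare,364.0
eating_disorders,,nonmedical,45.0
eating_disorders,,indirect,90.0
intellectual_disability,,healthcare,6409.0
intellectual_disability,,nonmedical,3203.0
personality_disorders,,healthcare,697.0
personality_disorders,,nonmedical,583.0
personality_disorders,,indirect,3979.0
sleep_disorders,,healthcare,396.0
sleep_disorders,,indirect,284.0
somatoform_disorders,,healthcare,426.0
somatoform_disorders,,indirect,465.0
traumatic_brain_injury,,healthcare,2412.0
traumatic_brain_injury,,nonmedical,830.0
traumatic_brain_injury,,indirect,4183.0
psychotic_disorders,,indirect,11705.0
anxiety_disorders,other_anxiety,healthcare,619.58
anxiety_disorders,other_anxiety,nonmedical,7.06
anxiety_disorders,other_anxiety,indirect,514.58
mood_disorders,unipolar,nonmedical,469.0
mood_disorders,bipolar,nonmedical,469.0
mood_disorders,bipolar,indirect,3117.03
neuromuscular_disorders,other_neuromuscular,healthcare,4077.04
neuromuscular_disorders,other_neuromuscular,nonmedical,1043.92
neuromuscular_disorders,other_neuromuscular,indirect,14649.26
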