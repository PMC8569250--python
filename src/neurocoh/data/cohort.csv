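subject_id,group,sex,age,paretic_hand,chronicity_months,stroke_type,lesion_location,ue_fma,rmt_pct_mso
Stroke01,active,M,62,R,4,Ischemic,Basal ganglia,10,100
Stroke02,active,M,70,L,8,Ischemic,Pons,37,70
Stroke03,active,M,57,R,8,Hemorrhagic,Frontal/parietal lobe,47,55
Stroke04,active,M,70,L,2,Ischemic,"Basal ganglia, corona radiata",14,100
Stroke05,active,F,85,L,1,Ischemic,Basal ganglia,62,55
Stroke06,active,F,66,R,1,Ischemic,Frontal/temporal/parietal lobe,4,100
Stroke07,active,M,77,L,1,Ischemic,"Centrum semiovale, corona radiata, basal ganglia",58,70
Stroke08,active,F,35,L,5,Ischemic,Frontal/parietal lobe,49,100
Stroke09,active,M,69,R,11,Ischemic,Corona radiata,18,100
Stroke10,active,M,46,L,5,Hemorrhagic,Posterior horn of lateral ventricle,27,100
Stroke11,active,M,72,R,1,Hemorrhagic,Parietal/temporal lobe,47,40
Stroke12,active,M,62,L,2,Ischemic,Pons,26,50
Stroke13,active,M,63,L,6,Ischemic,"Basal ganglia, corona radiata, centrum semiovale",12,100
Stroke14,active,M,75,L,4,Ischemic,Pons,5,100
Stroke15,active,M,67,L,2,Ischemic,Frontal/temporal/parietal lobe,4,100
StrokeC01,sham,F,65,R,7,Ischemic,"Basal ganglia, corona radiata",8,100
StrokeC02,sham,M,69,R,2,Ischemic,Basal ganglia,28,80
StrokeC03,sham,F,70,L,2,Ischemic,"Basal ganglia, corona radiata, frontal lobe",45,100
StrokeC04,sham,M,42,L,6,Hemorrhagic,Pons,21,100
StrokeC05,sham,F,79,R,2,Ischemic,Thalamus/occipital lobe,36,40
StrokeC06,sham,M,60,R,9,Ischemic,Frontal/parietal/temporal lobe,4,100
StrokeC07,sham,M,43,L,1,Ischemic,"Frontal/parietal lobe, basal ganglia, corona radiata",64,20
StrokeC08,sham,M,67,L,2,Ischemic,Frontal/parietal/temporal lobe,4,100
StrokeC09,sham,F,64,R,2,Hemorrhagic,Basal ganglia,12,50
StrokeC10,sham,M,64,L,1,Ischemic,"Corona radiata, basal ganglia, thalamus",49,78
StrokeC11,sham,M,72,L,2,Ischemic,"Basal ganglia, periventricular white matter",46,80
StrokeC12,sham,F,64,R,3,Ischemic,Frontal/temporal/parietal lobe,4,100
StrokeC13,sham,M,70,R,3,Ischemic,Basal ganglia,28,75
StrokeC14,sham,M,35,L,18,Hemorrhagic,Basal ganglia,24,100
StrokeC15,sham,F,52,L,1,Ischemic,Corona radiata,4,100
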