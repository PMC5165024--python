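# Reference cohort, clinical characteristics: 18 pediatric intracranial EEG
# patients (9 seizure-free, Engel 1; 9 seizure-persistent, Engel >= 2).
# Columns: engel = Engel outcome class; soz_pct = percent of channels in the
# seizure onset zone; analyzed_minutes = EEG minutes spanned by the sampled
# interictal spike segments; spikes = spikes analyzed (10,000 per segment).
patient,age_years,gender,mri,engel,implant,electrodes,soz_pct,analyzed_minutes,spikes
Pt01,9,M,LE,1,RF,126,6.35,1051.92,50000
Pt02,18,M,NL,3,LF,100,4.00,338.28,100000
Pt03,7,M,NL,4,RF,99,41.41,153.56,100000
Pt04,16,F,NL,4,RF,94,11.70,445.82,100000
Pt05,20,F,LE,1,"LF, LT",99,22.22,198.65,100000
Pt06,10,M,NL,3,LF,108,29.63,681.29,100000
Pt07,11,M,LE,3,LF,124,20.97,446.09,100000
Pt08,15,F,LE,3,RF,64,25.00,455.23,50000
Pt09,11,F,NL,1,RF,116,15.52,189.38,100000
Pt10,5,M,LE,1,LF,92,46.67,396.90,100000
Pt11,12,M,LE,1,L-Hemi,108,26.85,86.65,100000
Pt12,7,M,NL,4,RT,110,59.09,422.02,100000
Pt13,8,M,LE,4,RF,98,100.00,1028.38,100000
Pt14,6,F,LE,4,RF,104,49.04,797.29,100000
Pt15,16,M,NL,1,RF,116,9.48,2205.93,100000
Pt16,3,F,LE,1,RT,74,45.95,1494.38,100000
Pt17,8,M,NL,1,LT,107,27.10,916.07,100000
Pt18,14,M,LE,1,RF,84,28.57,700.18,100000
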