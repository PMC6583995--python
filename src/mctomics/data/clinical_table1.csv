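id,breed,age_years,sex,location,follow_up_days,status,patnaik_grade,grade_two_tier,ki67_index
S01,Dachshund,10,male,Limbs and tail,658,CS,3,2,7.95
S02,Labrador,11,female,Trunk,480,LA,1,1,2.92
S03,Poodle,15,female,Trunk,466,LA,1,1,2.36
S04,Golden Retriever,7,female,Limbs and tail,308,DT,2,1,23.41
S05,Pug,9,female,Limbs and tail,587,LA,2,1,5.28
S06,Pitbull,10,female,Abdomen,254,LA,2,1,3.65
S07,Labrador,11,female,Trunk,364,LA,2,1,4.87
S08,Cocker,13,female,Trunk,283,LA,2,1,1.88
S09,Labrador,9,male,Limbs and tail,390,LA,2,1,3.8
S10,Labrador,5,female,Limbs and tail,101,DT,2,2,15.48
S11,Golden Retriever,3,female,Inguinal,232,LA,2,1,0.30
S12,Labrador,10,male,Limbs and tail,130,DT,1,1,2.11
S13,Golden Retriever,9,male,Trunk,191,LA,2,1,5.21
S14,Mixed breed,13,male,Inguinal,1095,LA,2,1,2.89
S15,Pitbull,11,male,Abdomen,676,LA,1,1,3.43
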