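study_id,n_itt_active,drop_active,n_itt_passive,drop_passive,diff,method,multiple_imputation,maximum_likelihood
Bakker et al,234,146,78,25,N/A,ANOVA,Yes,No
Bidargaddi et al,192,106,195,88,"Yes, higher in active",t tests,Yes,No
Bostock et al,128,5,110,4,N/A,ANOVA,No,No
Carissoli et al,20,0,18,0,N/A,ANOVA,N/A,N/A
Champion et al,38,9,36,3,No,MLM,Yes,Yes
Enock et al,206,38,36,0,N/A,MLM,No,Yes
Faurholt-Jepsen et al,39,6,39,5,N/A,MLM,No,Unclear
Hall et al,76,34,25,13,N/A,MLM,No,Unclear
Horsch et al,74,29,77,15,N/A,MLM,Yes,Unclear
Ivanova et al,101,20,51,4,N/A,MLM,No,Yes
Kahn et al,80,1,80,0,N/A,t tests,No,No
Krafft et al,67,15,31,5,N/A,MLM,No,Yes
Kristjansdottir et al,70,23,70,33,N/A,t tests,No,No
Kuhn et al,62,11,58,6,No,ANOVA,Yes,No
Lee and Jung,102,25,104,18,N/A,ANOVA,No,No
Levin et al (a),12,0,11,0,N/A,MLM,No,Unclear
Levin et al (b),59,13,28,5,No,MLM,No,Unclear
Ludtke et al,45,10,45,6,No,ANOVA,Yes,No
Lukas and Berking,16,2,15,2,N/A,ANOVA,No,No
Ly et al (a),36,3,37,2,N/A,MLM,No,Yes
Ly et al (b),14,0,14,0,N/A,MLM,No,Yes
Marx,46,2,50,0,N/A,ANOVA,No,No
Miner et al,25,2,24,3,N/A,ANOVA,Yes,No
Moell et al,29,3,28,1,N/A,ANOVA,No,No
Oh et al,39,1,20,4,N/A,ANOVA,No,No
Pham et al,31,14,32,7,N/A,ANOVA,No,No
Proudfoot et al,242,116,230,32,"Yes, higher in active",MLM,Yes,Yes
Roepke et al,190,152,93,57,"Yes, higher in active",MLM,No,Yes
Rosen et al,57,17,55,7,"Yes, higher in active",MLM,No,Yes
Schlosser et al,22,3,21,0,N/A,ANOVA,No,No
Stjernsward and Hansson,196,60,202,42,N/A,ANOVA,Yes,No
Stolz et al,60,18,30,7,No,MLM,Yes,Yes
Tighe et al,31,2,30,0,N/A,ANOVA,No,No
van Emmerik et al,191,111,186,45,"Yes, higher in active",MLM,Yes,Unclear
Versluis et al,46,9,42,3,"Yes, higher in active",MLM,No,Unclear
Yang et al,45,3,43,4,N/A,ANOVA,No,No
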