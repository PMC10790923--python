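channel_id	source_label	detector_label	source_x	source_y	source_z	detector_x	detector_y	detector_z	separation_cm
1	Fz	AFZ	0.312	58.512	66.462	0.231	80.771	35.417	3.82
2	Fz	F2	0.312	58.512	66.462	29.514	57.602	59.540	3.02
3	Fz	FCz	0.312	58.512	66.462	0.376	27.390	88.668	3.82
4	Fz	F1	0.312	58.512	66.462	-27.495	56.931	60.342	2.85
5	CPz	Cz	0.386	-47.318	99.432	0.401	-9.167	100.244	3.82
6	CPz	CP2	0.386	-47.318	99.432	38.384	-47.073	90.695	3.90
7	CPz	Pz	0.386	-47.318	99.432	0.325	-81.115	82.615	3.77
8	CPz	CP1	0.386	-47.318	99.432	-35.515	-47.292	91.315	3.68
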