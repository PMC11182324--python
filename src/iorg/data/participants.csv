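subject_id,study_eye,diagnosis,inheritance_pattern,sex_at_birth,age_years,axial_length_mm,photon_density_um2
4710,OS,None,none,F,30,24.11,2.37e7
8941,OD,None,none,F,21,23.5,2.53e7
10397,OD,None,none,F,25,25.74,2.09e7
13604,OD,Amblyopia OS,none,F,30,22.28,2.77e7
15077,OD,None,none,F,26,23.92,2.42e7
17575,OS,None,none,F,40,25.27,2.11e7
23045,OD,None,none,F,26,22.99,2.62e7
23521,OD,None,none,M,64,25.99,1.86e7
33388,OS,None,none,M,36,23.15,2.54e7
36828,OD,None,none,M,35,24.46,2.28e7
50093,OS,None,none,M,24,25.21,2.19e7
54784,OD,None,none,F,24,23.06,2.61e7
56450,OS,None,none,F,31,24.7,2.25e7
64774,OS,None,none,F,25,23.77,2.45e7
88735,OS,None,none,F,24,23.67,2.48e7
13090,OS,Retinitis Pigmentosa,"USH2A, recessive",F,67,24.2,2.12e7
15660,OD,Retinitis Pigmentosa,Not Reported,M,48,23.57,2.38e7
33948,OD,Retinitis Pigmentosa,Unknown mutation,M,36,23.44,2.48e7
53885,OD,Retinitis Pigmentosa,"RP, dominant RHO mutation",F,61,25.11,2.02e7
60151,OD,Ushers Syndrome,"USH2A, recessive",F,45,23.14,2.49e7
64010,OD,Retinitis Pigmentosa,"RP1, dominant",F,55,23.29,2.39e7
89385,OS,Retinitis Pigmentosa,Not Reported,M,58,25.07,2.04e7
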