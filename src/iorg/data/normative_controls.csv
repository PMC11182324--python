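metric,eccentricity_deg,mean,sd
NND,1.0,3.64,0.39
NND,1.5,4.13,0.35
NND,2.0,4.62,0.35
NND,4.0,6.26,0.48
NND,8.0,8.47,0.39
OS_length,1.0,30.2,1.6
OS_length,1.5,28.0,1.6
OS_length,2.0,26.0,2.36
OS_length,4.0,22.0,3.34
OS_length,8.0,16.9,3.63
iORG_amplitude,1.0,36.8,8.71
iORG_amplitude,1.5,33.0,7.53
iORG_amplitude,2.0,33.9,3.03
iORG_amplitude,4.0,34.7,7.35
iORG_amplitude,8.0,28.04,6.75
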