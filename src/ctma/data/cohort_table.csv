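subject,COMX_mm,COMY_mm,COMZ_mm,ROTX_deg,ROTY_deg,ROTZ_deg
1,0.877,2.944,0.913,1.074,0.94,-0.526
2,-5.476,-4.561,-0.614,-1.031,1.43,-4.293
3,-0.668,-0.074,1.373,-0.313,-0.086,-3.019
4,-2.632,0.779,0.822,0.427,1.184,-0.55
5,-1.575,0.093,-5.403,-0.105,0.997,-7.425
6,-0.853,-2.179,0.769,-1.008,0.536,-0.725
7,-3.77,-6.513,7.955,-1.829,0.897,1.988
8,-1.332,-0.023,1.693,-0.387,0.487,3.431
9,-0.301,3.699,-0.353,1.067,0.23,1.047
10,-0.527,-1.553,1.949,-0.537,0.413,-1.814
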