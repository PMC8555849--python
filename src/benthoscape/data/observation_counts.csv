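role,type,source,n,Rock,Mixed,Sand,Mud
build,Grab,CHS,127770,58899,13688,34753,20430
build,Grab,NRCan,8938,0,0,4241,4697
build,Dive,DFO,44809,21250,7626,13464,2469
build,ROV,DFO,10856,4073,2205,3200,1378
build,Marsh,CHS,5214,0,0,0,5214
evaluation,Dive,DFO,4974,2892,543,974,565
evaluation,Camera,DFO,2143,421,491,654,577
evaluation,ROV,DFO,6064,1477,1479,633,2475
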