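run_id,DSPC,SM-102,cholesterol,DMG-PEG2000,is_validation
M01,19,65,15,1,0
M02,5,35,50,10,0
M03,18.3,35.9,35.8,10,0
M04,5,53,38,4,0
M05,40,15,35,10,0
M06,40,29.5,29.5,1,0
M07,14.9,51.2,26.2,7.7,0
M08,5,65,29,1,0
M09,23,15,58,4,0
M10,8.3,65,16.7,10,0
M11,40,39.5,15,5.5,0
M12,5,20,65,10,0
M13,29.9,40.7,26.2,3.2,0
M14,5,29,65,1,0
M15,24.7,26.2,45.9,3.2,0
MS,10,50,38.5,1.5,1
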