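patient_id,eye,st_scotoma,it_scotoma,st_db,it_db,gh_db,st_score,it_score,st_rnfl_um,it_rnfl_um
S091,OS,Yes,Yes,-31,-7,-4.5,ONL,ONL,27,41
S101,OD,Yes,Yes,-20,-1,-5.3,ONL,ONL,61,68
S096,OD,Yes,Yes,-13,-3,-5.3,ONL,ONL,51,51
S095,OS,Yes,Yes,-5,-2,-0.3,ONL,ONL,65,91
S089,OS,Yes,Yes,-1,-7,-8.8,BL,ONL,93,28
S100,OS,Yes,Yes,-4,-2,-4.2,ONL,ONL,82,58
S102,OS,Yes,No,-33,-3,-1.7,ONL,ONL,28,95
S093,OS,Yes,No,-10,-4,-3.1,ONL,WNL,46,129
S102,OD,Yes,No,-3,-1,-1.7,ONL,WNL,55,125
S103,OD,No,Yes,-2,-33,-3.5,WNL,ONL,125,64
S092,OS,No,Yes,-4,-29,-5.3,BL,ONL,92,47
S097,OS,No,Yes,-1,-14,-5.2,WNL,ONL,120,75
S100,OD,No,Yes,-5,-6,-4.3,ONL,ONL,76,42
S088,OS,No,Yes,-6,-5,-7,BL,ONL,92,79
S090,OS,No,Yes,-3,-4,-4.8,BL,ONL,94,51
S095,OD,No,Yes,-4,-4,-1.8,ONL,BL,83,94
S105,OS,No,No,-4,-10,-5.7,BL,BL,83,91
S093,OD,No,No,-7,-4,-0.7,WNL,WNL,107,150
S094,OS,No,No,-3,-5,-2.4,WNL,ONL,116,52
S104,OD,No,No,-2,-5,-3.5,BL,ONL,99,75
S097,OD,No,No,-2,-4,-2.4,WNL,WNL,104,133
S099,OS,No,No,-2,-3,-5.2,WNL,BL,108,97
S099,OD,No,No,-2,-3,-6.2,WNL,WNL,109,117
S098,OS,No,No,-3,-2,-3.3,BL,WNL,76,96
S101,OS,No,No,-2,-2,-5.8,WNL,WNL,106,122
S091,OD,No,No,-1,0,-1,ONL,ONL,65,69
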