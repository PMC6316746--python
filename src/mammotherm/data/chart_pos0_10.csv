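# mammotherm chart v1
# provenance: paper_fixture
# position_mm: 0.0,10.0
# r1_grid_mm: 40.0,50.0,60.0,70.0,80.0
# r2_grid_mm: 1.0,2.0,3.0,4.0,5.0,6.0,7.0,8.0,9.0,10.0
position_x_mm,position_y_mm,R1_mm,R2_mm,delta_T_C,delta_T_C_2dp,provenance
0.0,10.0,40.0,1.0,0.22,0.22,paper_fixture
0.0,10.0,40.0,2.0,0.27,0.27,paper_fixture
0.0,10.0,40.0,3.0,0.23,0.23,paper_fixture
0.0,10.0,40.0,4.0,0.24,0.24,paper_fixture
0.0,10.0,40.0,5.0,0.29,0.29,paper_fixture
0.0,10.0,40.0,6.0,0.3,0.30,paper_fixture
0.0,10.0,40.0,7.0,0.31,0.31,paper_fixture
0.0,10.0,40.0,8.0,0.35,0.35,paper_fixture
0.0,10.0,40.0,9.0,0.33,0.33,paper_fixture
0.0,10.0,40.0,10.0,0.32,0.32,paper_fixture
0.0,10.0,50.0,1.0,0.25,0.25,paper_fixture
0.0,10.0,50.0,2.0,0.28,0.28,paper_fixture
0.0,10.0,50.0,3.0,0.31,0.31,paper_fixture
0.0,10.0,50.0,4.0,0.33,0.33,paper_fixture
0.0,10.0,50.0,5.0,0.41,0.41,paper_fixture
0.0,10.0,50.0,6.0,0.42,0.42,paper_fixture
0.0,10.0,50.0,7.0,0.42,0.42,paper_fixture
0.0,10.0,50.0,8.0,0.49,0.49,paper_fixture
0.0,10.0,50.0,9.0,0.53,0.53,paper_fixture
0.0,10.0,50.0,10.0,0.48,0.48,paper_fixture
0.0,10.0,60.0,1.0,0.27,0.27,paper_fixture
0.0,10.0,60.0,2.0,0.32,0.32,paper_fixture
0.0,10.0,60.0,3.0,0.36,0.36,paper_fixture
0.0,10.0,60.0,4.0,0.39,0.39,paper_fixture
0.0,10.0,60.0,5.0,0.48,0.48,paper_fixture
0.0,10.0,60.0,6.0,0.49,0.49,paper_fixture
0.0,10.0,60.0,7.0,0.49,0.49,paper_fixture
0.0,10.0,60.0,8.0,0.48,0.48,paper_fixture
0.0,10.0,60.0,9.0,0.48,0.48,paper_fixture
0.0,10.0,60.0,10.0,0.47,0.47,paper_fixture
0.0,10.0,70.0,1.0,0.31,0.31,paper_fixture
0.0,10.0,70.0,2.0,0.36,0.36,paper_fixture
0.0,10.0,70.0,3.0,0.4,0.40,paper_fixture
0.0,10.0,70.0,4.0,0.43,0.43,paper_fixture
0.0,10.0,70.0,5.0,0.54,0.54,paper_fixture
0.0,10.0,70.0,6.0,0.55,0.55,paper_fixture
0.0,10.0,70.0,7.0,0.55,0.55,paper_fixture
0.0,10.0,70.0,8.0,0.55,0.55,paper_fixture
0.0,10.0,70.0,9.0,0.55,0.55,paper_fixture
0.0,10.0,70.0,10.0,0.53,0.53,paper_fixture
0.0,10.0,80.0,1.0,0.33,0.33,paper_fixture
0.0,10.0,80.0,2.0,0.38,0.38,paper_fixture
0.0,10.0,80.0,3.0,0.42,0.42,paper_fixture
0.0,10.0,80.0,4.0,0.47,0.47,paper_fixture
0.0,10.0,80.0,5.0,0.57,0.57,paper_fixture
0.0,10.0,80.0,6.0,0.61,0.61,paper_fixture
0.0,10.0,80.0,7.0,0.61,0.61,paper_fixture
0.0,10.0,80.0,8.0,0.6,0.60,paper_fixture
0.0,10.0,80.0,9.0,0.62,0.62,paper_fixture
0.0,10.0,80.0,10.0,0.58,0.58,paper_fixture
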