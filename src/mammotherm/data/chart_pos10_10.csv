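# mammotherm chart v1
# provenance: paper_fixture
# position_mm: 10.0,10.0
# r1_grid_mm: 40.0,50.0,60.0,70.0,80.0
# r2_grid_mm: 1.0,2.0,3.0,4.0,5.0,6.0,7.0,8.0,9.0,10.0
position_x_mm,position_y_mm,R1_mm,R2_mm,delta_T_C,delta_T_C_2dp,provenance
10.0,10.0,40.0,1.0,0.35,0.35,paper_fixture
10.0,10.0,40.0,2.0,0.37,0.37,paper_fixture
10.0,10.0,40.0,3.0,0.4,0.40,paper_fixture
10.0,10.0,40.0,4.0,0.42,0.42,paper_fixture
10.0,10.0,40.0,5.0,0.43,0.43,paper_fixture
10.0,10.0,40.0,6.0,0.44,0.44,paper_fixture
10.0,10.0,40.0,7.0,0.41,0.41,paper_fixture
10.0,10.0,40.0,8.0,0.48,0.48,paper_fixture
10.0,10.0,40.0,9.0,0.31,0.31,paper_fixture
10.0,10.0,40.0,10.0,0.32,0.32,paper_fixture
10.0,10.0,50.0,1.0,0.42,0.42,paper_fixture
10.0,10.0,50.0,2.0,0.44,0.44,paper_fixture
10.0,10.0,50.0,3.0,0.46,0.46,paper_fixture
10.0,10.0,50.0,4.0,0.48,0.48,paper_fixture
10.0,10.0,50.0,5.0,0.52,0.52,paper_fixture
10.0,10.0,50.0,6.0,0.52,0.52,paper_fixture
10.0,10.0,50.0,7.0,0.5,0.50,paper_fixture
10.0,10.0,50.0,8.0,0.47,0.47,paper_fixture
10.0,10.0,50.0,9.0,0.48,0.48,paper_fixture
10.0,10.0,50.0,10.0,0.49,0.49,paper_fixture
10.0,10.0,60.0,1.0,0.46,0.46,paper_fixture
10.0,10.0,60.0,2.0,0.49,0.49,paper_fixture
10.0,10.0,60.0,3.0,0.51,0.51,paper_fixture
10.0,10.0,60.0,4.0,0.54,0.54,paper_fixture
10.0,10.0,60.0,5.0,0.56,0.56,paper_fixture
10.0,10.0,60.0,6.0,0.57,0.57,paper_fixture
10.0,10.0,60.0,7.0,0.56,0.56,paper_fixture
10.0,10.0,60.0,8.0,0.54,0.54,paper_fixture
10.0,10.0,60.0,9.0,0.51,0.51,paper_fixture
10.0,10.0,60.0,10.0,0.46,0.46,paper_fixture
10.0,10.0,70.0,1.0,0.49,0.49,paper_fixture
10.0,10.0,70.0,2.0,0.52,0.52,paper_fixture
10.0,10.0,70.0,3.0,0.55,0.55,paper_fixture
10.0,10.0,70.0,4.0,0.59,0.59,paper_fixture
10.0,10.0,70.0,5.0,0.62,0.62,paper_fixture
10.0,10.0,70.0,6.0,0.63,0.63,paper_fixture
10.0,10.0,70.0,7.0,0.64,0.64,paper_fixture
10.0,10.0,70.0,8.0,0.61,0.61,paper_fixture
10.0,10.0,70.0,9.0,0.56,0.56,paper_fixture
10.0,10.0,70.0,10.0,0.52,0.52,paper_fixture
10.0,10.0,80.0,1.0,0.51,0.51,paper_fixture
10.0,10.0,80.0,2.0,0.56,0.56,paper_fixture
10.0,10.0,80.0,3.0,0.6,0.60,paper_fixture
10.0,10.0,80.0,4.0,0.63,0.63,paper_fixture
10.0,10.0,80.0,5.0,0.67,0.67,paper_fixture
10.0,10.0,80.0,6.0,0.68,0.68,paper_fixture
10.0,10.0,80.0,7.0,0.66,0.66,paper_fixture
10.0,10.0,80.0,8.0,0.56,0.56,paper_fixture
10.0,10.0,80.0,9.0,0.63,0.63,paper_fixture
10.0,10.0,80.0,10.0,0.58,0.58,paper_fixture
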