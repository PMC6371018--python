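# radionuclide: Y90-synthetic
# voxel_size_mm: 3.0
# units: mGy/(MBq*s)
i,j,k,S_value
-3,-3,-3,8.26700048e-04
-3,-3,-2,1.51675115e-03
-3,-3,-1,2.25779986e-03
-3,-3,0,2.59581552e-03
-3,-3,1,2.25779986e-03
-3,-3,2,1.51675115e-03
-3,-3,3,8.26700048e-04
-3,-2,-3,1.51675115e-03
-3,-2,-2,2.99619398e-03
-3,-2,-1,4.73546864e-03
-3,-2,0,5.57564513e-03
-3,-2,1,4.73546864e-03
-3,-2,2,2.99619398e-03
-3,-2,3,1.51675115e-03
-3,-1,-3,2.25779986e-03
-3,-1,-2,4.73546864e-03
-3,-1,-1,7.88624270e-03
-3,-1,0,9.49092773e-03
-3,-1,1,7.88624270e-03
-3,-1,2,4.73546864e-03
-3,-1,3,2.25779986e-03
-3,0,-3,2.59581552e-03
-3,0,-2,5.57564513e-03
-3,0,-1,9.49092773e-03
-3,0,0,1.15313517e-02
-3,0,1,9.49092773e-03
-3,0,2,5.57564513e-03
-3,0,3,2.59581552e-03
-3,1,-3,2.25779986e-03
-3,1,-2,4.73546864e-03
-3,1,-1,7.88624270e-03
-3,1,0,9.49092773e-03
-3,1,1,7.88624270e-03
-3,1,2,4.73546864e-03
-3,1,3,2.25779986e-03
-3,2,-3,1.51675115e-03
-3,2,-2,2.99619398e-03
-3,2,-1,4.73546864e-03
-3,2,0,5.57564513e-03
-3,2,1,4.73546864e-03
-3,2,2,2.99619398e-03
-3,2,3,1.51675115e-03
-3,3,-3,8.26700048e-04
-3,3,-2,1.51675115e-03
-3,3,-1,2.25779986e-03
-3,3,0,2.59581552e-03
-3,3,1,2.25779986e-03
-3,3,2,1.51675115e-03
-3,3,3,8.26700048e-04
-2,-3,-3,1.51675115e-03
-2,-3,-2,2.99619398e-03
-2,-3,-1,4.73546864e-03
-2,-3,0,5.57564513e-03
-2,-3,1,4.73546864e-03
-2,-3,2,2.99619398e-03
-2,-3,3,1.51675115e-03
-2,-2,-3,2.99619398e-03
-2,-2,-2,6.60711845e-03
-2,-2,-1,1.15313517e-02
-2,-2,0,1.41675907e-02
-2,-2,1,1.15313517e-02
-2,-2,2,6.60711845e-03
-2,-2,3,2.99619398e-03
-2,-1,-3,4.73546864e-03
-2,-1,-2,1.15313517e-02
-2,-1,-1,2.23244361e-02
-2,-1,0,2.88407116e-02
-2,-1,1,2.23244361e-02
-2,-1,2,1.15313517e-02
-2,-1,3,4.73546864e-03
-2,0,-3,5.57564513e-03
-2,0,-2,1.41675907e-02
-2,0,-1,2.88407116e-02
-2,0,0,3.82854359e-02
-2,0,1,2.88407116e-02
-2,0,2,1.41675907e-02
-2,0,3,5.57564513e-03
-2,1,-3,4.73546864e-03
-2,1,-2,1.15313517e-02
-2,1,-1,2.23244361e-02
-2,1,0,2.88407116e-02
-2,1,1,2.23244361e-02
-2,1,2,1.15313517e-02
-2,1,3,4.73546864e-03
-2,2,-3,2.99619398e-03
-2,2,-2,6.60711845e-03
-2,2,-1,1.15313517e-02
-2,2,0,1.41675907e-02
-2,2,1,1.15313517e-02
-2,2,2,6.60711845e-03
-2,2,3,2.99619398e-03
-2,3,-3,1.51675115e-03
-2,3,-2,2.99619398e-03
-2,3,-1,4.73546864e-03
-2,3,0,5.57564513e-03
-2,3,1,4.73546864e-03
-2,3,2,2.99619398e-03
-2,3,3,1.51675115e-03
-1,-3,-3,2.25779986e-03
-1,-3,-2,4.73546864e-03
-1,-3,-1,7.88624270e-03
-1,-3,0,9.49092773e-03
-1,-3,1,7.88624270e-03
-1,-3,2,4.73546864e-03
-1,-3,3,2.25779986e-03
-1,-2,-3,4.73546864e-03
-1,-2,-2,1.15313517e-02
-1,-2,-1,2.23244361e-02
-1,-2,0,2.88407116e-02
-1,-2,1,2.23244361e-02
-1,-2,2,1.15313517e-02
-1,-2,3,4.73546864e-03
-1,-1,-3,7.88624270e-03
-1,-1,-2,2.23244361e-02
-1,-1,-1,5.28051429e-02
-1,-1,0,7.73246880e-02
-1,-1,1,5.28051429e-02
-1,-1,2,2.23244361e-02
-1,-1,3,7.88624270e-03
-1,0,-3,9.49092773e-03
-1,0,-2,2.88407116e-02
-1,0,-1,7.73246880e-02
-1,0,0,1.27112123e-01
-1,0,1,7.73246880e-02
-1,0,2,2.88407116e-02
-1,0,3,9.49092773e-03
-1,1,-3,7.88624270e-03
-1,1,-2,2.23244361e-02
-1,1,-1,5.28051429e-02
-1,1,0,7.73246880e-02
-1,1,1,5.28051429e-02
-1,1,2,2.23244361e-02
-1,1,3,7.88624270e-03
-1,2,-3,4.73546864e-03
-1,2,-2,1.15313517e-02
-1,2,-1,2.23244361e-02
-1,2,0,2.88407116e-02
-1,2,1,2.23244361e-02
-1,2,2,1.15313517e-02
-1,2,3,4.73546864e-03
-1,3,-3,2.25779986e-03
-1,3,-2,4.73546864e-03
-1,3,-1,7.88624270e-03
-1,3,0,9.49092773e-03
-1,3,1,7.88624270e-03
-1,3,2,4.73546864e-03
-1,3,3,2.25779986e-03
0,-3,-3,2.59581552e-03
0,-3,-2,5.57564513e-03
0,-3,-1,9.49092773e-03
0,-3,0,1.15313517e-02
0,-3,1,9.49092773e-03
0,-3,2,5.57564513e-03
0,-3,3,2.59581552e-03
0,-2,-3,5.57564513e-03
0,-2,-2,1.41675907e-02
0,-2,-1,2.88407116e-02
0,-2,0,3.82854359e-02
0,-2,1,2.88407116e-02
0,-2,2,1.41675907e-02
0,-2,3,5.57564513e-03
0,-1,-3,9.49092773e-03
0,-1,-2,2.88407116e-02
0,-1,-1,7.73246880e-02
0,-1,0,1.27112123e-01
0,-1,1,7.73246880e-02
0,-1,2,2.88407116e-02
0,-1,3,9.49092773e-03
0,0,-3,1.15313517e-02
0,0,-2,3.82854359e-02
0,0,-1,1.27112123e-01
0,0,0,4.22027112e-01
0,0,1,1.27112123e-01
0,0,2,3.82854359e-02
0,0,3,1.15313517e-02
0,1,-3,9.49092773e-03
0,1,-2,2.88407116e-02
0,1,-1,7.73246880e-02
0,1,0,1.27112123e-01
0,1,1,7.73246880e-02
0,1,2,2.88407116e-02
0,1,3,9.49092773e-03
0,2,-3,5.57564513e-03
0,2,-2,1.41675907e-02
0,2,-1,2.88407116e-02
0,2,0,3.82854359e-02
0,2,1,2.88407116e-02
0,2,2,1.41675907e-02
0,2,3,5.57564513e-03
0,3,-3,2.59581552e-03
0,3,-2,5.57564513e-03
0,3,-1,9.49092773e-03
0,3,0,1.15313517e-02
0,3,1,9.49092773e-03
0,3,2,5.57564513e-03
0,3,3,2.59581552e-03
1,-3,-3,2.25779986e-03
1,-3,-2,4.73546864e-03
1,-3,-1,7.88624270e-03
1,-3,0,9.49092773e-03
1,-3,1,7.88624270e-03
1,-3,2,4.73546864e-03
1,-3,3,2.25779986e-03
1,-2,-3,4.73546864e-03
1,-2,-2,1.15313517e-02
1,-2,-1,2.23244361e-02
1,-2,0,2.88407116e-02
1,-2,1,2.23244361e-02
1,-2,2,1.15313517e-02
1,-2,3,4.73546864e-03
1,-1,-3,7.88624270e-03
1,-1,-2,2.23244361e-02
1,-1,-1,5.28051429e-02
1,-1,0,7.73246880e-02
1,-1,1,5.28051429e-02
1,-1,2,2.23244361e-02
1,-1,3,7.88624270e-03
1,0,-3,9.49092773e-03
1,0,-2,2.88407116e-02
1,0,-1,7.73246880e-02
1,0,0,1.27112123e-01
1,0,1,7.73246880e-02
1,0,2,2.88407116e-02
1,0,3,9.49092773e-03
1,1,-3,7.88624270e-03
1,1,-2,2.23244361e-02
1,1,-1,5.28051429e-02
1,1,0,7.73246880e-02
1,1,1,5.28051429e-02
1,1,2,2.23244361e-02
1,1,3,7.88624270e-03
1,2,-3,4.73546864e-03
1,2,-2,1.15313517e-02
1,2,-1,2.23244361e-02
1,2,0,2.88407116e-02
1,2,1,2.23244361e-02
1,2,2,1.15313517e-02
1,2,3,4.73546864e-03
1,3,-3,2.25779986e-03
1,3,-2,4.73546864e-03
1,3,-1,7.88624270e-03
1,3,0,9.49092773e-03
1,3,1,7.88624270e-03
1,3,2,4.73546864e-03
1,3,3,2.25779986e-03
2,-3,-3,1.51675115e-03
2,-3,-2,2.99619398e-03
2,-3,-1,4.73546864e-03
2,-3,0,5.57564513e-03
2,-3,1,4.73546864e-03
2,-3,2,2.99619398e-03
2,-3,3,1.51675115e-03
2,-2,-3,2.99619398e-03
2,-2,-2,6.60711845e-03
2,-2,-1,1.15313517e-02
2,-2,0,1.41675907e-02
2,-2,1,1.15313517e-02
2,-2,2,6.60711845e-03
2,-2,3,2.99619398e-03
2,-1,-3,4.73546864e-03
2,-1,-2,1.15313517e-02
2,-1,-1,2.23244361e-02
2,-1,0,2.88407116e-02
2,-1,1,2.23244361e-02
2,-1,2,1.15313517e-02
2,-1,3,4.73546864e-03
2,0,-3,5.57564513e-03
2,0,-2,1.41675907e-02
2,0,-1,2.88407116e-02
2,0,0,3.82854359e-02
2,0,1,2.88407116e-02
2,0,2,1.41675907e-02
2,0,3,5.57564513e-03
2,1,-3,4.73546864e-03
2,1,-2,1.15313517e-02
2,1,-1,2.23244361e-02
2,1,0,2.88407116e-02
2,1,1,2.23244361e-02
2,1,2,1.15313517e-02
2,1,3,4.73546864e-03
2,2,-3,2.99619398e-03
2,2,-2,6.60711845e-03
2,2,-1,1.15313517e-02
2,2,0,1.41675907e-02
2,2,1,1.15313517e-02
2,2,2,6.60711845e-03
2,2,3,2.99619398e-03
2,3,-3,1.51675115e-03
2,3,-2,2.99619398e-03
2,3,-1,4.73546864e-03
2,3,0,5.57564513e-03
2,3,1,4.73546864e-03
2,3,2,2.99619398e-03
2,3,3,1.51675115e-03
3,-3,-3,8.26700048e-04
3,-3,-2,1.51675115e-03
3,-3,-1,2.25779986e-03
3,-3,0,2.59581552e-03
3,-3,1,2.25779986e-03
3,-3,2,1.51675115e-03
3,-3,3,8.26700048e-04
3,-2,-3,1.51675115e-03
3,-2,-2,2.99619398e-03
3,-2,-1,4.73546864e-03
3,-2,0,5.57564513e-03
3,-2,1,4.73546864e-03
3,-2,2,2.99619398e-03
3,-2,3,1.51675115e-03
3,-1,-3,2.25779986e-03
3,-1,-2,4.73546864e-03
3,-1,-1,7.88624270e-03
3,-1,0,9.49092773e-03
3,-1,1,7.88624270e-03
3,-1,2,4.73546864e-03
3,-1,3,2.25779986e-03
3,0,-3,2.59581552e-03
3,0,-2,5.57564513e-03
3,0,-1,9.49092773e-03
3,0,0,1.15313517e-02
3,0,1,9.49092773e-03
3,0,2,5.57564513e-03
3,0,3,2.59581552e-03
3,1,-3,2.25779986e-03
3,1,-2,4.73546864e-03
3,1,-1,7.88624270e-03
3,1,0,9.49092773e-03
3,1,1,7.88624270e-03
3,1,2,4.73546864e-03
3,1,3,2.25779986e-03
3,2,-3,1.51675115e-03
3,2,-2,2.99619398e-03
3,2,-1,4.73546864e-03
3,2,0,5.57564513e-03
3,2,1,4.73546864e-03
3,2,2,2.99619398e-03
3,2,3,1.51675115e-03
3,3,-3,8.26700048e-04
3,3,-2,1.51675115e-03
3,3,-1,2.25779986e-03
3,3,0,2.59581552e-03
3,3,1,2.25779986e-03
3,3,2,1.51675115e-03
3,3,3,8.26700048e-04
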