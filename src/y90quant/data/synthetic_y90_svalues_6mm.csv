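# radionuclide: Y90-synthetic
# voxel_size_mm: 6.0
# units: mGy/(MBq*s)
i,j,k,S_value
-3,-3,-3,1.12009351e-06
-3,-3,-2,3.77039649e-06
-3,-3,-1,8.35466884e-06
-3,-3,0,1.10434815e-05
-3,-3,1,8.35466884e-06
-3,-3,2,3.77039649e-06
-3,-3,3,1.12009351e-06
-3,-2,-3,3.77039649e-06
-3,-2,-2,1.47128975e-05
-3,-2,-1,3.67522799e-05
-3,-2,0,5.09505181e-05
-3,-2,1,3.67522799e-05
-3,-2,2,1.47128975e-05
-3,-2,3,3.77039649e-06
-3,-1,-3,8.35466884e-06
-3,-1,-2,3.67522799e-05
-3,-1,-1,1.01929204e-04
-3,-1,0,1.47630363e-04
-3,-1,1,1.01929204e-04
-3,-1,2,3.67522799e-05
-3,-1,3,8.35466884e-06
-3,0,-3,1.10434815e-05
-3,0,-2,5.09505181e-05
-3,0,-1,1.47630363e-04
-3,0,0,2.17930889e-04
-3,0,1,1.47630363e-04
-3,0,2,5.09505181e-05
-3,0,3,1.10434815e-05
-3,1,-3,8.35466884e-06
-3,1,-2,3.67522799e-05
-3,1,-1,1.01929204e-04
-3,1,0,1.47630363e-04
-3,1,1,1.01929204e-04
-3,1,2,3.67522799e-05
-3,1,3,8.35466884e-06
-3,2,-3,3.77039649e-06
-3,2,-2,1.47128975e-05
-3,2,-1,3.67522799e-05
-3,2,0,5.09505181e-05
-3,2,1,3.67522799e-05
-3,2,2,1.47128975e-05
-3,2,3,3.77039649e-06
-3,3,-3,1.12009351e-06
-3,3,-2,3.77039649e-06
-3,3,-1,8.35466884e-06
-3,3,0,1.10434815e-05
-3,3,1,8.35466884e-06
-3,3,2,3.77039649e-06
-3,3,3,1.12009351e-06
-2,-3,-3,3.77039649e-06
-2,-3,-2,1.47128975e-05
-2,-3,-1,3.67522799e-05
-2,-3,0,5.09505181e-05
-2,-3,1,3.67522799e-05
-2,-3,2,1.47128975e-05
-2,-3,3,3.77039649e-06
-2,-2,-3,1.47128975e-05
-2,-2,-2,7.15455360e-05
-2,-2,-1,2.17930889e-04
-2,-2,0,3.28965503e-04
-2,-2,1,2.17930889e-04
-2,-2,2,7.15455360e-05
-2,-2,3,1.47128975e-05
-2,-1,-3,3.67522799e-05
-2,-1,-2,2.17930889e-04
-2,-1,-1,8.16806813e-04
-2,-1,0,1.36323366e-03
-2,-1,1,8.16806813e-04
-2,-1,2,2.17930889e-04
-2,-1,3,3.67522799e-05
-2,0,-3,5.09505181e-05
-2,0,-2,3.28965503e-04
-2,0,-1,1.36323366e-03
-2,0,0,2.40229063e-03
-2,0,1,1.36323366e-03
-2,0,2,3.28965503e-04
-2,0,3,5.09505181e-05
-2,1,-3,3.67522799e-05
-2,1,-2,2.17930889e-04
-2,1,-1,8.16806813e-04
-2,1,0,1.36323366e-03
-2,1,1,8.16806813e-04
-2,1,2,2.17930889e-04
-2,1,3,3.67522799e-05
-2,2,-3,1.47128975e-05
-2,2,-2,7.15455360e-05
-2,2,-1,2.17930889e-04
-2,2,0,3.28965503e-04
-2,2,1,2.17930889e-04
-2,2,2,7.15455360e-05
-2,2,3,1.47128975e-05
-2,3,-3,3.77039649e-06
-2,3,-2,1.47128975e-05
-2,3,-1,3.67522799e-05
-2,3,0,5.09505181e-05
-2,3,1,3.67522799e-05
-2,3,2,1.47128975e-05
-2,3,3,3.77039649e-06
-1,-3,-3,8.35466884e-06
-1,-3,-2,3.67522799e-05
-1,-3,-1,1.01929204e-04
-1,-3,0,1.47630363e-04
-1,-3,1,1.01929204e-04
-1,-3,2,3.67522799e-05
-1,-3,3,8.35466884e-06
-1,-2,-3,3.67522799e-05
-1,-2,-2,2.17930889e-04
-1,-2,-1,8.16806813e-04
-1,-2,0,1.36323366e-03
-1,-2,1,8.16806813e-04
-1,-2,2,2.17930889e-04
-1,-2,3,3.67522799e-05
-1,-1,-3,1.01929204e-04
-1,-1,-2,8.16806813e-04
-1,-1,-1,4.56994319e-03
-1,-1,0,9.79929223e-03
-1,-1,1,4.56994319e-03
-1,-1,2,8.16806813e-04
-1,-1,3,1.01929204e-04
-1,0,-3,1.47630363e-04
-1,0,-2,1.36323366e-03
-1,0,-1,9.79929223e-03
-1,0,0,2.64808733e-02
-1,0,1,9.79929223e-03
-1,0,2,1.36323366e-03
-1,0,3,1.47630363e-04
-1,1,-3,1.01929204e-04
-1,1,-2,8.16806813e-04
-1,1,-1,4.56994319e-03
-1,1,0,9.79929223e-03
-1,1,1,4.56994319e-03
-1,1,2,8.16806813e-04
-1,1,3,1.01929204e-04
-1,2,-3,3.67522799e-05
-1,2,-2,2.17930889e-04
-1,2,-1,8.16806813e-04
-1,2,0,1.36323366e-03
-1,2,1,8.16806813e-04
-1,2,2,2.17930889e-04
-1,2,3,3.67522799e-05
-1,3,-3,8.35466884e-06
-1,3,-2,3.67522799e-05
-1,3,-1,1.01929204e-04
-1,3,0,1.47630363e-04
-1,3,1,1.01929204e-04
-1,3,2,3.67522799e-05
-1,3,3,8.35466884e-06
0,-3,-3,1.10434815e-05
0,-3,-2,5.09505181e-05
0,-3,-1,1.47630363e-04
0,-3,0,2.17930889e-04
0,-3,1,1.47630363e-04
0,-3,2,5.09505181e-05
0,-3,3,1.10434815e-05
0,-2,-3,5.09505181e-05
0,-2,-2,3.28965503e-04
0,-2,-1,1.36323366e-03
0,-2,0,2.40229063e-03
0,-2,1,1.36323366e-03
0,-2,2,3.28965503e-04
0,-2,3,5.09505181e-05
0,-1,-3,1.47630363e-04
0,-1,-2,1.36323366e-03
0,-1,-1,9.79929223e-03
0,-1,0,2.64808733e-02
0,-1,1,9.79929223e-03
0,-1,2,1.36323366e-03
0,-1,3,1.47630363e-04
0,0,-3,2.17930889e-04
0,0,-2,2.40229063e-03
0,0,-1,2.64808733e-02
0,0,0,2.91903337e-01
0,0,1,2.64808733e-02
0,0,2,2.40229063e-03
0,0,3,2.17930889e-04
0,1,-3,1.47630363e-04
0,1,-2,1.36323366e-03
0,1,-1,9.79929223e-03
0,1,0,2.64808733e-02
0,1,1,9.79929223e-03
0,1,2,1.36323366e-03
0,1,3,1.47630363e-04
0,2,-3,5.09505181e-05
0,2,-2,3.28965503e-04
0,2,-1,1.36323366e-03
0,2,0,2.40229063e-03
0,2,1,1.36323366e-03
0,2,2,3.28965503e-04
0,2,3,5.09505181e-05
0,3,-3,1.10434815e-05
0,3,-2,5.09505181e-05
0,3,-1,1.47630363e-04
0,3,0,2.17930889e-04
0,3,1,1.47630363e-04
0,3,2,5.09505181e-05
0,3,3,1.10434815e-05
1,-3,-3,8.35466884e-06
1,-3,-2,3.67522799e-05
1,-3,-1,1.01929204e-04
1,-3,0,1.47630363e-04
1,-3,1,1.01929204e-04
1,-3,2,3.67522799e-05
1,-3,3,8.35466884e-06
1,-2,-3,3.67522799e-05
1,-2,-2,2.17930889e-04
1,-2,-1,8.16806813e-04
1,-2,0,1.36323366e-03
1,-2,1,8.16806813e-04
1,-2,2,2.17930889e-04
1,-2,3,3.67522799e-05
1,-1,-3,1.01929204e-04
1,-1,-2,8.16806813e-04
1,-1,-1,4.56994319e-03
1,-1,0,9.79929223e-03
1,-1,1,4.56994319e-03
1,-1,2,8.16806813e-04
1,-1,3,1.01929204e-04
1,0,-3,1.47630363e-04
1,0,-2,1.36323366e-03
1,0,-1,9.79929223e-03
1,0,0,2.64808733e-02
1,0,1,9.79929223e-03
1,0,2,1.36323366e-03
1,0,3,1.47630363e-04
1,1,-3,1.01929204e-04
1,1,-2,8.16806813e-04
1,1,-1,4.56994319e-03
1,1,0,9.79929223e-03
1,1,1,4.56994319e-03
1,1,2,8.16806813e-04
1,1,3,1.01929204e-04
1,2,-3,3.67522799e-05
1,2,-2,2.17930889e-04
1,2,-1,8.16806813e-04
1,2,0,1.36323366e-03
1,2,1,8.16806813e-04
1,2,2,2.17930889e-04
1,2,3,3.67522799e-05
1,3,-3,8.35466884e-06
1,3,-2,3.67522799e-05
1,3,-1,1.01929204e-04
1,3,0,1.47630363e-04
1,3,1,1.01929204e-04
1,3,2,3.67522799e-05
1,3,3,8.35466884e-06
2,-3,-3,3.77039649e-06
2,-3,-2,1.47128975e-05
2,-3,-1,3.67522799e-05
2,-3,0,5.09505181e-05
2,-3,1,3.67522799e-05
2,-3,2,1.47128975e-05
2,-3,3,3.77039649e-06
2,-2,-3,1.47128975e-05
2,-2,-2,7.15455360e-05
2,-2,-1,2.17930889e-04
2,-2,0,3.28965503e-04
2,-2,1,2.17930889e-04
2,-2,2,7.15455360e-05
2,-2,3,1.47128975e-05
2,-1,-3,3.67522799e-05
2,-1,-2,2.17930889e-04
2,-1,-1,8.16806813e-04
2,-1,0,1.36323366e-03
2,-1,1,8.16806813e-04
2,-1,2,2.17930889e-04
2,-1,3,3.67522799e-05
2,0,-3,5.09505181e-05
2,0,-2,3.28965503e-04
2,0,-1,1.36323366e-03
2,0,0,2.40229063e-03
2,0,1,1.36323366e-03
2,0,2,3.28965503e-04
2,0,3,5.09505181e-05
2,1,-3,3.67522799e-05
2,1,-2,2.17930889e-04
2,1,-1,8.16806813e-04
2,1,0,1.36323366e-03
2,1,1,8.16806813e-04
2,1,2,2.17930889e-04
2,1,3,3.67522799e-05
2,2,-3,1.47128975e-05
2,2,-2,7.15455360e-05
2,2,-1,2.17930889e-04
2,2,0,3.28965503e-04
2,2,1,2.17930889e-04
2,2,2,7.15455360e-05
2,2,3,1.47128975e-05
2,3,-3,3.77039649e-06
2,3,-2,1.47128975e-05
2,3,-1,3.67522799e-05
2,3,0,5.09505181e-05
2,3,1,3.67522799e-05
2,3,2,1.47128975e-05
2,3,3,3.77039649e-06
3,-3,-3,1.12009351e-06
3,-3,-2,3.77039649e-06
3,-3,-1,8.35466884e-06
3,-3,0,1.10434815e-05
3,-3,1,8.35466884e-06
3,-3,2,3.77039649e-06
3,-3,3,1.12009351e-06
3,-2,-3,3.77039649e-06
3,-2,-2,1.47128975e-05
3,-2,-1,3.67522799e-05
3,-2,0,5.09505181e-05
3,-2,1,3.67522799e-05
3,-2,2,1.47128975e-05
3,-2,3,3.77039649e-06
3,-1,-3,8.35466884e-06
3,-1,-2,3.67522799e-05
3,-1,-1,1.01929204e-04
3,-1,0,1.47630363e-04
3,-1,1,1.01929204e-04
3,-1,2,3.67522799e-05
3,-1,3,8.35466884e-06
3,0,-3,1.10434815e-05
3,0,-2,5.09505181e-05
3,0,-1,1.47630363e-04
3,0,0,2.17930889e-04
3,0,1,1.47630363e-04
3,0,2,5.09505181e-05
3,0,3,1.10434815e-05
3,1,-3,8.35466884e-06
3,1,-2,3.67522799e-05
3,1,-1,1.01929204e-04
3,1,0,1.47630363e-04
3,1,1,1.01929204e-04
3,1,2,3.67522799e-05
3,1,3,8.35466884e-06
3,2,-3,3.77039649e-06
3,2,-2,1.47128975e-05
3,2,-1,3.67522799e-05
3,2,0,5.09505181e-05
3,2,1,3.67522799e-05
3,2,2,1.47128975e-05
3,2,3,3.77039649e-06
3,3,-3,1.12009351e-06
3,3,-2,3.77039649e-06
3,3,-1,8.35466884e-06
3,3,0,1.10434815e-05
3,3,1,8.35466884e-06
3,3,2,3.77039649e-06
3,3,3,1.12009351e-06
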