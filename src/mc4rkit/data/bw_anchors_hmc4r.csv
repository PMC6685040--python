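helix,anchor_position,anchor_residue,note
1,62,N,N1.50 of the TM1 consensus
2,90,D,D2.50 sodium-site aspartate
3,147,R,R3.50 of the D[R]Y motif
4,174,W,W4.50 tryptophan
5,204,M,5.50 by alignment column; melanocortin receptors carry Met where most class A receptors have Pro
6,260,P,P6.50 of the CWxP motif
7,299,P,P7.50 of the DPxxY motif
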