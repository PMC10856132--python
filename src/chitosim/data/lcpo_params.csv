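# LCPO neighbor-overlap parameters (Weiser/Shenkin/Still parameterization)
# key: element, n_bonded_heavy, hybridization; radii are vdW (A), probe 1.4 A
# P1..P4 weight the isolated-sphere area, pairwise overlaps, neighbor-pair
# overlaps and the mixed term. Hydrogens carry zero area by convention.
element,n_heavy,hybrid,radius,P1,P2,P3,P4
C,1,sp3,1.70,0.77887,-0.28063,-0.0012968,0.00039328
C,2,sp3,1.70,0.56482,-0.19608,-0.0010219,0.0002658
C,3,sp3,1.70,0.23348,-0.072627,-0.00020079,0.00007967
C,4,sp3,1.70,0.00000,0.00000,0.00000,0.00000
C,2,sp2,1.70,0.51245,-0.15966,-0.00019781,0.00016392
C,3,sp2,1.70,0.070344,-0.019015,-0.000022009,0.000016875
O,1,sp3,1.60,0.77914,-0.25262,-0.0016056,0.00035071
O,2,sp3,1.60,0.49392,-0.16038,-0.00015512,0.00016453
O,1,sp2,1.60,0.68563,-0.18680,-0.0013557,0.00023743
O,0,sp3,1.60,1.00000,0.00000,0.00000,0.00000
N,1,sp3,1.65,0.73511,-0.22116,-0.00089148,0.0002523
N,2,sp3,1.65,0.41102,-0.12254,-0.000075448,0.00011804
N,3,sp3,1.65,0.062577,-0.017874,-0.00008312,0.000019849
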