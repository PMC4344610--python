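compound,pair,source,intensity,reference
1,H1(Fuc)-H3(GlA),experimental,1,H1(Fuc)-H3(GlA)
1,H1(Fuc)-H3(GlA),SASA,1,H1(Fuc)-H3(GlA)
1,H1(Fuc)-H3(GlA),water,1,H1(Fuc)-H3(GlA)
1,H1(Fuc)-H4(GlA),experimental,0,H1(Fuc)-H3(GlA)
1,H1(Fuc)-H4(GlA),SASA,0.26,H1(Fuc)-H3(GlA)
1,H1(Fuc)-H4(GlA),water,0.05,H1(Fuc)-H3(GlA)
1,H1(Fuc)-H2(GlA),experimental,0,H1(Fuc)-H3(GlA)
1,H1(Fuc)-H2(GlA),SASA,0.12,H1(Fuc)-H3(GlA)
1,H1(Fuc)-H2(GlA),water,0.01,H1(Fuc)-H3(GlA)
4,H1(Fuc)-H3(GlA),experimental,1,H1(Fuc)-H3(GlA)
4,H1(Fuc)-H3(GlA),SASA,1,H1(Fuc)-H3(GlA)
4,H1(Fuc)-H3(GlA),water,1,H1(Fuc)-H3(GlA)
4,H1(Fuc)-H4(GlA),experimental,0,H1(Fuc)-H3(GlA)
4,H1(Fuc)-H4(GlA),SASA,0.33,H1(Fuc)-H3(GlA)
4,H1(Fuc)-H4(GlA),water,0,H1(Fuc)-H3(GlA)
4,H1(Fuc)-H2(GlA),experimental,0,H1(Fuc)-H3(GlA)
4,H1(Fuc)-H2(GlA),SASA,0.09,H1(Fuc)-H3(GlA)
4,H1(Fuc)-H2(GlA),water,0.01,H1(Fuc)-H3(GlA)
4,H1(Fuc')-H3(Fuc),experimental,0.62,H1(Fuc)-H3(GlA)
4,H1(Fuc')-H3(Fuc),SASA,0.81,H1(Fuc)-H3(GlA)
4,H1(Fuc')-H3(Fuc),water,0.7,H1(Fuc)-H3(GlA)
4,H1(Fuc')-H4(Fuc),experimental,0.7,H1(Fuc)-H3(GlA)
4,H1(Fuc')-H4(Fuc),SASA,3.0,H1(Fuc)-H3(GlA)
4,H1(Fuc')-H4(Fuc),water,1,H1(Fuc)-H3(GlA)
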