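compound,linkage,torsion_kind,source,value_hz
1,Fuc-GlA,phi,experimental,3.8
1,Fuc-GlA,phi,in_vacuo,4.0
1,Fuc-GlA,phi,SASA,3.4
1,Fuc-GlA,phi,water,3.2
1,Fuc-GlA,psi,experimental,2.5
1,Fuc-GlA,psi,in_vacuo,3.8
1,Fuc-GlA,psi,SASA,2.7
1,Fuc-GlA,psi,water,2.5
2,Fuc-GlA,phi,experimental,2.7
2,Fuc-GlA,phi,in_vacuo,4.0
2,Fuc-GlA,phi,SASA,3.6
2,Fuc-GlA,phi,water,3.2
2,Fuc-GlA,psi,experimental,2.9
2,Fuc-GlA,psi,in_vacuo,3.7
2,Fuc-GlA,psi,SASA,2.3
2,Fuc-GlA,psi,water,2.4
3,Fuc-GlA,phi,experimental,3.0
3,Fuc-GlA,phi,in_vacuo,4.0
3,Fuc-GlA,phi,SASA,3.3
3,Fuc-GlA,phi,water,3.2
3,Fuc-GlA,psi,experimental,2.7
3,Fuc-GlA,psi,in_vacuo,3.8
3,Fuc-GlA,psi,SASA,2.7
3,Fuc-GlA,psi,water,2.6
4,Fuc-GlA,phi,experimental,3.6
4,Fuc-GlA,phi,in_vacuo,4.0
4,Fuc-GlA,phi,SASA,3.2
4,Fuc-GlA,phi,water,3.3
4,Fuc-GlA,psi,experimental,3.0
4,Fuc-GlA,psi,in_vacuo,3.8
4,Fuc-GlA,psi,SASA,2.9
4,Fuc-GlA,psi,water,3.4
4,Fuc-Fuc,phi,experimental,2.8
4,Fuc-Fuc,phi,in_vacuo,3.5
4,Fuc-Fuc,phi,SASA,2.7
4,Fuc-Fuc,phi,water,2.5
4,Fuc-Fuc,psi,experimental,2.5
4,Fuc-Fuc,psi,in_vacuo,3.2
4,Fuc-Fuc,psi,SASA,2.6
4,Fuc-Fuc,psi,water,2.5
5,Fuc-GlA,phi,experimental,2.7
5,Fuc-GlA,phi,in_vacuo,4.0
5,Fuc-GlA,phi,SASA,3.2
5,Fuc-GlA,phi,water,3.2
5,Fuc-GlA,psi,experimental,2.5
5,Fuc-GlA,psi,in_vacuo,3.7
5,Fuc-GlA,psi,SASA,2.4
5,Fuc-GlA,psi,water,2.4
5,Fuc-Fuc,phi,experimental,2.6
5,Fuc-Fuc,phi,in_vacuo,3.3
5,Fuc-Fuc,phi,SASA,3.2
5,Fuc-Fuc,phi,water,2.8
5,Fuc-Fuc,psi,experimental,2.9
5,Fuc-Fuc,psi,in_vacuo,3.1
5,Fuc-Fuc,psi,SASA,3.4
5,Fuc-Fuc,psi,water,2.6
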