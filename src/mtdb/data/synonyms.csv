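synonym,compound_id
"p,p'-DDE","p,p'-DDE"
"4,4'-DDE","p,p'-DDE"
"pp-DDE","p,p'-DDE"
"p p DDE","p,p'-DDE"
"o,p'-DDE","o,p'-DDE"
"2,4'-DDE","o,p'-DDE"
"p,p'-DDT","p,p'-DDT"
"4,4'-DDT","p,p'-DDT"
"o,p'-DDT","o,p'-DDT"
"2,4'-DDT","o,p'-DDT"
"p,p'-DDD","p,p'-DDD"
"4,4'-DDD","p,p'-DDD"
"p,p'-TDE","p,p'-DDD"
hexachlorobenzene,HCB
HCB,HCB
dieldrin,dieldrin
HEOD,dieldrin
trans-nonachlor,trans-nonachlor
cis-nonachlor,cis-nonachlor
oxychlordane,oxychlordane
heptachlor epoxide,heptachlor epoxide
mirex,mirex
"gamma-HCH",lindane
lindane,lindane
"alpha-HCH",alpha-HCH
"beta-HCH",beta-HCH
PFOS,PFOS
perfluorooctane sulfonate,PFOS
perfluorooctanesulfonic acid,PFOS
PFOA,PFOA
perfluorooctanoic acid,PFOA
PFNA,PFNA
perfluorononanoic acid,PFNA
benzo[a]pyrene,benzo[a]pyrene
BaP,benzo[a]pyrene
phenanthrene,phenanthrene
pyrene,pyrene
"2,3,7,8-TCDD","2,3,7,8-TCDD"
TCDD,"2,3,7,8-TCDD"
HBCD,HBCDD
hexabromocyclododecane,HBCDD
TPHP,TPHP
triphenyl phosphate,TPHP
DEHP,DEHP
"bis(2-ethylhexyl) phthalate",DEHP
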