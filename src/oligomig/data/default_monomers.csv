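# Default monomer library: common starting substances of polyester can coatings.
# Hydroxyacids are stored in the ring-opened, hydrated acid form (caprolactone
# as 6-hydroxyhexanoic acid C6H12O3) so that one water is removed per ester bond.
id,abbreviation,name,formula,class,aromatic
PA,PA,phthalic acid,C8H6O4,diacid,true
IPA,IPA,isophthalic acid,C8H6O4,diacid,true
TPA,TPA,terephthalic acid,C8H6O4,diacid,true
AA,AA,adipic acid,C6H10O4,diacid,false
TMA,TMA,trimellitic acid,C9H6O6,triacid,true
NPG,NPG,neopentyl glycol,C5H12O2,diol,false
EG,EG,ethylene glycol,C2H6O2,diol,false
DEG,DEG,diethylene glycol,C4H10O3,diol,false
HD,HD,"1,6-hexanediol",C6H14O2,diol,false
BD,BD,"1,4-butanediol",C4H10O2,diol,false
BD13,BD13,"1,3-butanediol",C4H10O2,diol,false
MPO,MPO,"2-methyl-1,3-propanediol",C4H10O2,diol,false
PDO,PDO,"1,3-propanediol",C3H8O2,diol,false
CHDM,CHDM,"1,4-cyclohexanedimethanol",C8H16O2,diol,false
TMP,TMP,trimethylolpropane,C6H14O3,triol,false
GLY,GLY,glycerol,C3H8O3,triol,false
CL,CL,caprolactone (ring-opened),C6H12O3,hydroxyacid,false
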