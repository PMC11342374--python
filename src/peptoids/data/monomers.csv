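code,name,category,side_chain,lipid_carbons,shape,pka_list
Aet,2-aminoethyl,cationic,*CCN,0,none,amine:base:10.7
Apr,3-aminopropyl,cationic,*CCCN,0,none,amine:base:10.5
Mae,2-(methylamino)ethyl,cationic,*CCNC,0,none,amine:base:10.4
Gnd,3-guanidinopropyl,cationic,*CCCNC(N)=N,0,none,guanidinium:base:12.5
Dma,2-(dimethylamino)ethyl,cationic,*CCN(C)C,0,none,amine:base:9.2
Dmp,3-(dimethylamino)propyl,cationic,*CCCN(C)C,0,none,amine:base:9.5
Pip,2-(piperidin-1-yl)ethyl,cationic,*CCN1CCCCC1,0,none,amine:base:9.6
Pyr,2-(pyrrolidin-1-yl)ethyl,cationic,*CCN1CCCC1,0,none,amine:base:9.8
Dea,2-(bis(2-hydroxyethyl)amino)ethyl,cationic,*CCN(CCO)CCO,0,none,amine:base:6.9
Apd,"1,3-dihydroxypropan-2-yl",cationic,*C(CO)CO,0,none,amine:base:5.6
Mor,2-morpholinoethyl,cationic,*CCN1CCOCC1,0,none,amine:base:6.2
Imi,2-(1H-imidazol-4-yl)ethyl,cationic,*CCc1c[nH]cn1,0,none,imidazolium:base:6.9
Hye,2-hydroxyethyl,hydrophilic,*CCO,0,none,
Hyp,3-hydroxypropyl,hydrophilic,*CCCO,0,none,
Dhp,"2,3-dihydroxypropyl",hydrophilic,*CC(O)CO,0,none,
Nme,2-methoxyethyl,hydrophilic,*CCOC,0,none,
Nmp,3-methoxypropyl,hydrophilic,*CCCOC,0,none,
Mpe,2-(2-methoxyethoxy)ethyl,hydrophilic,*CCOCCOC,0,none,
Teg,2-(2-(2-methoxyethoxy)ethoxy)ethyl,hydrophilic,*CCOCCOCCOC,0,none,
Ame,2-acetamidoethyl,hydrophilic,*CCNC(C)=O,0,none,
Mso,2-(methylsulfinyl)ethyl,hydrophilic,*CCS(C)=O,0,none,
Cme,carboxymethyl,anionic,*CC(=O)O,0,none,carboxylate:acid:3.8
Cet,2-carboxyethyl,anionic,*CCC(=O)O,0,none,carboxylate:acid:4.2
Sup,3-sulfopropyl,anionic,*CCCS(=O)(=O)O,0,none,sulfonate:acid:1.5
Hex,hexyl,lipid,*CCCCCC,6,linear,
Oct,octyl,lipid,*CCCCCCCC,8,linear,
Dec,decyl,lipid,*CCCCCCCCCC,10,linear,
Dod,dodecyl,lipid,*CCCCCCCCCCCC,12,linear,
Ehx,2-ethylhexyl,lipid,*CC(CC)CCCC,8,branched,
Ole,oleyl,lipid,*CCCCCCCCC=CCCCCCCCC,18,unsaturated,
Sar,methyl,other,*C,0,none,
Eth,ethyl,other,*CC,0,none,
Npr,propyl,other,*CCC,0,none,
Nbu,butyl,other,*CCCC,0,none,
Phe,2-phenylethyl,other,*CCc1ccccc1,0,none,
Bzl,benzyl,other,*Cc1ccccc1,0,none,
Nap,naphthalen-2-ylmethyl,other,*Cc1ccc2ccccc2c1,0,none,
Cyh,cyclohexylmethyl,other,*CC1CCCCC1,0,none,
Fur,furan-2-ylmethyl,other,*Cc1ccco1,0,none,
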