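strain_id,genus_species,pathogenic,score
HER1022,Escherichia coli,False,-
HER1024,Escherichia coli,False,+
HER1025,Escherichia coli,False,+
HER1036,Escherichia coli,False,++++
HER1037,Escherichia coli,False,+
HER1040,Escherichia coli,False,+
HER1077,Escherichia coli,False,+
HER1128,Escherichia coli,False,-
HER1129,Escherichia coli,False,-
HER1139,Escherichia coli,False,+
HER1144,Escherichia coli,False,-
HER1155,Escherichia coli,False,++++
HER1213,Escherichia coli,False,-
HER1217,Escherichia coli,False,+
HER1218,Escherichia coli,False,-
HER1219,Escherichia coli,False,-
HER1221,Escherichia coli,False,+
HER1222,Escherichia coli,False,++++
HER1240,Escherichia coli,False,+
HER1252,Escherichia coli,False,+
HER1253,Escherichia coli,False,-
HER1271,Escherichia coli,False,+
HER1275,Escherichia coli,False,+
HER1290,Escherichia coli,False,-
HER1299,Escherichia coli,False,+
HER1315,Escherichia coli,False,++++
HER1337,Escherichia coli,False,+
HER1366,Escherichia coli,False,+
HER1374,Escherichia coli,False,-
HER1375,Escherichia coli,False,++++
HER1382,Escherichia coli,False,+
HER1383,Escherichia coli,False,+
HER1392,Escherichia coli,False,-
HER1393,Escherichia coli,False,-
HER1445,Escherichia coli,False,-
HER1446,Escherichia coli,False,-
HER1462,Escherichia coli,False,+
HER1536,Escherichia coli,False,++++
HER1176,Escherichia coli,True,+++
HER1255,Escherichia coli,True,-
HER1256,Escherichia coli,True,-
HER1257,Escherichia coli,True,-
HER1258,Escherichia coli,True,-
HER1259,Escherichia coli,True,-
HER1260,Escherichia coli,True,-
HER1261,Escherichia coli,True,-
HER1262,Escherichia coli,True,-
HER1263,Escherichia coli,True,-
HER1264,Escherichia coli,True,-
HER1265,Escherichia coli,True,-
HER1266,Escherichia coli,True,-
HER1267,Escherichia coli,True,-
HER1268,Escherichia coli,True,-
HER1269,Escherichia coli,True,-
HER1270,Escherichia coli,True,-
ST130,Escherichia coli,True,++++
ST120,Escherichia coli,True,-
ST110,Escherichia coli,True,++
ST100,Escherichia coli,True,++
BW,Escherichia coli,True,-
HER1043,Shigella sonnei,True,+
HER1031,Shigella dysenteriae,True,-
HER1020,Shigella dysenteriae,True,-
HER1045,Salmonella paratyphi,True,-
HER1038,Salmonella typhi,True,-
CF3,Citrobacter freundii,True,-
CF4,Citrobacter freundii,True,-
CF5,Citrobacter freundii,True,-
CF7,Citrobacter freundii,True,-
CF8,Citrobacter freundii,True,-
Sa1,Citrobacter freundii,True,-
Sa6,Citrobacter freundii,True,-
Sa59,Citrobacter freundii,True,-
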