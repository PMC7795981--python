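reference_nm,assignment,provenance
970,water second overtone of OH stretching; water species with two hydrogen bonds,stage-1 variance band
975,water second overtone of OH stretching,raw-spectrum water band
988,lactic acid absorption near the water second overtone,stage-1 variance band
998,water species with three hydrogen bonds; negatively correlated with pH,stage-1 variance band
1000,stage-one variance band in the water second-overtone region,stage-1 variance band
1026-1032,casein / milk-protein absorption,protein-band literature
1090,water second-overtone region band prominent early in fermentation,stage-1 variance band
1150,overtone of the water combination band,raw-spectrum water band
1361,proton hydrates / solvated hydronium ion; water hydration shells,stage-1 variance band
1420,intermediate (hydration) water appearing in the set gel,stage-3 variance band
1425,hydration water; water hydrating proteins,aquaphotomics literature
1428,glucose-related band; polysaccharide (EPS) building block,carbohydrate literature
1450,water first overtone of OH stretching,raw-spectrum water band
1453,intermediate / adsorbed water appearing in the set gel,stage-3 variance band
1455,physically adsorbed water; also OH first overtone of histidine,aquaphotomics literature
1668,bonded OH of H3O+ stretch in small proton hydrates H+(H2O)4,protonated-water literature
1670-1675,proton hydrate H+(H2O)6; strong early-fermentation feature extending toward 1900 nm,stage-1 variance band
1683,exopolysaccharide (EPS) absorbance,EPS literature
1722,exopolysaccharide (EPS) absorbance,EPS literature
1752,exopolysaccharide (EPS) absorbance,EPS literature
1840,combination of OH stretching and CO bonds; water-EPS interaction; microbial-mass marker,stage-1 variance band
1910,water combination band (OH stretch + HOH bend),raw-spectrum water band
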