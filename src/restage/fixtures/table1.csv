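category,compound,average_er,sd
VASODILATOR,VINPOCETINE,1.36,0.66
VASODILATOR,ISOXSUPRINE,1.54,0.23
VASODILATOR,NYLIDRIN,1.60,0.00
STEROIDS,CYPROTERONE,1.29,0.38
STEROIDS,CHLORMADINONE ACETATE,1.69,0.30
STEROIDS,ESTRADIOL (2X),1.30,0.17
STEROIDS,FLUDROCORTISONE ACETATE,1.35,0.05
FLAVONOIDS,BIOCHANIN A,2.13,0.29
FLAVONOIDS,QUERCITRIN,1.40,0.29
FLAVONOIDS,5-METHYL-7-METHOXYISOFLAVONE,1.53,0.23
ANTIHYPERTENSIVE ACE INHIBITOR,PERINDOPRIL ERBUMINE,1.30,0.21
ANTIHYPERTENSIVE ACE INHIBITOR,TRANDOLAPRIL,1.30,0.13
ANTIHYPERTENSIVE SARTAN,LOSARTAN,1.30,0.18
ANTIHYPERTENSIVE SARTAN,OLMESARTAN,1.31,0.17
ANTIHYPERTENSIVE DIURETIC,DIAZOXIDE,1.32,0.05
ANTIHYPERTENSIVE DIURETIC,VERATRINE SULFATE,1.40,0.20
ANTIHYPERTENSIVE BETA-BLOCKER,ALPRENOLOL,1.37,0.25
ANTIINFLAMMATORY,HYDROXYTOLUIC ACID,1.33,0.06
ANTIINFLAMMATORY,"S-(1,2-DICARBOXYETHYL)GLUTATHIONE",1.32,0.21
ANTIINFLAMMATORY,VULPINIC ACID,1.37,0.35
ANTIINFLAMMATORY,DIACERIN,1.33,0.06
ANTIINFLAMMATORY,FLUOCINOLONE ACETONIDE,1.40,0.30
ANTIINFLAMMATORY,BECLOMETHASONE DIPROPIONATE,1.51,0.14
ANTIBACTERIC,FENAMISAL,1.33,0.21
ANTIBACTERIC,KANAMYCIN A SULPHATE,1.32,0.03
ANTIBACTERIC,GENTAMICIN SULPHATE,1.44,0.15
ANTIBACTERIC,HYGROMYCIN B,1.33,0.25
ANTIHISTAMINIC,TRIPELENNAMINE CITRATE,1.40,0.26
ANTIHISTAMINIC,DIPHENYLPYRALINE HYDROCHLORIDE,1.48,0.16
ANTIHISTAMINIC,ORPHENADRINE CITRATE,1.49,0.14
ANTI-DEPRESSIVE,ESCITALOPRAM OXALATE,1.43,0.12
ANTIOXIDANT,EDARAVONE,1.33,0.15
MUSCARINIC ANTAGONIST,HYOSCYAMINE,1.53,0.12
HYPOLIPIDEMIC,LOVASTATIN,1.23,0.10
HYPOLIPIDEMIC,NIACIN,1.47,0.06
CATHARTIC,PHENOLPHTHALEIN,1.67,0.29
COMT INHIBITOR,"3,5-DINITROCATECHOL (OR-486)",1.37,0.06
MUSCARINIC AGONIST,AMINOBENZTROPINE,1.33,0.06
PSYCHOSTIMULANT,URIDINE TRIPHOSPHATE TRISODIUM,1.40,0.10
ANTI-INFECTIVE,CINEOLE,1.38,0.35
ANTIARYTHMIC,LIDOCAINE HYDROCHLORIDE,1.55,0.21
LIPASE INHIBITOR,ORLISTAT,1.32,0.21
ANTIFUNGAL,AVOCADYNE ACETATE,1.43,0.12
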