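compound,role,prolif_raw,prolif_se,prolif_score,prolif_total,cgt_raw,cgt_se,cgt_score,cgt_total,mbp_raw,mbp_se,mbp_score,mbp_total,total_score,single_measurement
PDGF,control,3.17,0.98,10.00,31.75,,,,,,,,,,false
T3 + T4,control,,,,,4.21,0.49,3.00,12.63,8.95,1.98,5.00,44.75,,false
VULPINIC ACID,compound,2.11,0.59,10.00,21.08,11.19,4.49,3.00,33.58,60.00,54.54,5.00,300.00,354.65,false
LOVASTATIN,compound,2.94,0.26,10.00,29.36,22.86,20.35,3.00,68.57,58.25,55.69,5.00,291.24,389.17,false
EDARAVONE,compound,3.52,0.64,10.00,35.19,23.08,16.09,3.00,69.25,48.11,42.19,5.00,240.55,344.99,false
FENAMISAL,compound,3.15,0.41,10.00,31.55,9.52,5.06,3.00,28.57,36.89,29.81,5.00,184.47,244.59,false
5-METHYL-7-METHOXYISOFLAVONE,compound,7.05,1.36,10.00,70.54,8.86,0.34,3.00,26.59,35.95,20.86,5.00,179.73,276.86,false
LOSARTAN,compound,1.14,0.23,10.00,11.44,11.11,10.23,3.00,33.34,23.24,21.14,5.00,116.21,160.98,false
CHLORMADINONE ACETATE,compound,0.66,0.24,10.00,6.61,10.09,0.60,3.00,30.26,16.79,1.26,5.00,83.96,120.83,false
BIOCHANIN A,compound,1.24,0.08,10.00,12.38,3.53,3.39,3.00,10.58,7.96,7.15,5.00,39.79,62.75,false
CYPROTERONE,compound,1.25,0.34,10.00,12.49,2.46,0.13,3.00,7.39,7.65,0.06,5.00,38.23,58.12,false
OLMESARTAN,compound,0.79,0.17,10.00,7.88,4.06,3.08,3.00,12.19,6.49,4.47,5.00,32.44,52.50,false
FLUOCINOLONE ACETONIDE,compound,0.59,0.17,10.00,5.89,2.40,0.13,3.00,7.21,5.95,0.48,5.00,29.74,42.83,false
TRANDOLAPRIL,compound,2.84,1.24,10.00,28.35,6.06,5.44,3.00,18.17,5.86,5.11,5.00,29.31,75.83,false
QUERCITRIN,compound,3.90,0.44,10.00,38.96,4.68,1.76,3.00,14.05,5.10,3.09,5.00,25.48,78.48,false
URIDINE TRIPHOSPHATE TRISODIUM,compound,4.80,0.36,10.00,47.99,3.75,0.21,3.00,11.26,5.02,0.41,5.00,25.10,84.35,false
DIPHENYLPYRALINE HYDROCHLORIDE,compound,3.65,1.35,10.00,36.46,3.10,2.01,3.00,9.29,4.90,3.23,5.00,24.52,70.27,false
VERATRINE SULFATE,compound,3.23,0.81,10.00,32.33,4.09,0.17,3.00,12.27,4.82,0.27,5.00,24.11,68.72,false
"3,5-DINITROCATECHOL",compound,5.55,1.35,10.00,55.47,4.74,0.39,3.00,14.22,4.76,0.19,5.00,23.78,93.48,false
HYGROMYCIN B,compound,3.66,0.45,10.00,36.65,4.46,4.08,3.00,13.37,4.65,3.69,5.00,23.25,73.27,false
ESCITALOPRAM OXALATE,compound,3.86,0.56,10.00,38.63,3.91,3.31,3.00,11.72,3.89,1.53,5.00,19.46,69.80,false
DIAZOXIDE,compound,1.34,0.11,10.00,13.37,3.31,2.32,3.00,9.92,3.67,1.25,5.00,18.35,41.65,false
ESTRADIOL,compound,1.85,0.61,10.00,18.47,1.53,0.34,3.00,4.59,2.75,1.10,5.00,13.76,36.83,false
AMINOBENZTROPINE,compound,5.77,1.17,10.00,57.67,1.48,,3.00,4.44,2.58,,5.00,12.92,75.04,true
DIACERIN,compound,1.28,0.36,10.00,12.76,0.19,,3.00,0.58,2.56,,5.00,12.81,26.16,true
PERINDOPRIL ERBUMINE,compound,2.33,0.32,10.00,23.28,1.76,0.11,3.00,5.27,2.45,0.10,5.00,12.23,40.78,false
PHENOLPHTHALEIN,compound,1.21,0.10,10.00,12.11,2.85,1.68,3.00,8.55,2.44,1.53,5.00,12.19,32.85,false
ORPHENADRINE CITRATE,compound,1.08,0.39,10.00,10.84,0.41,,3.00,1.24,1.66,,5.00,8.29,20.36,true
BECLOMETHASONE DIPROPIONATE,compound,0.48,0.07,10.00,4.78,1.06,,3.00,3.17,1.55,,5.00,7.74,15.69,true
NIACIN,compound,0.77,0.21,10.00,7.75,0.70,,3.00,2.11,1.35,,5.00,6.73,16.58,true
FLUDROCORTISONE ACETATE,compound,0.74,0.13,10.00,7.41,0.76,,3.00,2.28,1.28,,5.00,6.41,16.10,true
AVOCADYNE ACETATE,compound,1.09,0.15,10.00,10.88,1.20,,3.00,3.61,1.10,,5.00,5.48,19.97,true
KANAMYCIN A SULPHATE,compound,0.95,0.20,10.00,9.45,1.50,,3.00,4.51,1.03,,5.00,5.15,19.11,true
LIDOCAINE HYDROCHLORIDE,compound,2.43,0.14,10.00,24.29,1.10,,3.00,3.30,1.02,,5.00,5.09,32.67,true
"S-(1,2-DICARBOXYETHYL)GLUTATHIONE",compound,1.37,0.15,10.00,13.66,0.71,,3.00,2.12,0.85,,5.00,4.23,20.01,true
HYOSCYAMINE,compound,1.35,0.40,10.00,13.52,0.43,,3.00,1.30,0.84,,5.00,4.18,19.00,true
VINPOCETINE,compound,0.83,0.26,10.00,8.31,0.96,,3.00,2.89,0.62,,5.00,3.11,14.31,true
GENTAMICIN SULPHATE,compound,1.16,0.21,10.00,11.59,0.67,,3.00,2.02,0.54,,5.00,2.69,16.30,true
ORLISTAT,compound,1.87,0.36,10.00,18.66,0.70,,3.00,2.09,0.53,,5.00,2.65,23.41,true
ISOXSUPRINE,compound,1.20,0.40,10.00,12.00,0.95,,3.00,2.84,0.49,,5.00,2.46,17.31,true
CINEOLE,compound,1.03,0.30,10.00,10.26,0.63,,3.00,1.90,0.45,,5.00,2.24,14.40,true
TRIPELENNAMINE CITRATE,compound,3.61,0.92,10.00,36.08,0.21,,3.00,0.63,0.22,,5.00,1.10,37.81,true
NYLIDRIN,compound,0.94,0.07,10.00,9.38,0.09,,3.00,0.27,0.21,,5.00,1.04,10.68,true
ALPRENOLOL,compound,3.57,0.33,10.00,35.69,0.23,,3.00,0.70,0.09,,5.00,0.43,36.83,true
HYDROXYTOLUIC ACID,compound,2.26,0.29,10.00,22.57,0.22,,3.00,0.65,0.05,,5.00,0.24,23.45,true
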