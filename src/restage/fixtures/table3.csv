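compound,role,mbp_mean,mbp_se,mbp_p,mbp_significant,cgt_mean,cgt_se,cgt_p,cgt_significant
CTR,baseline,1,0,,false,1,0,,false
T3 + T4,pos_control,2.85,0.45,0.01,true,2.65,0.9,0.09,false
VULPINIC ACID,compound,1.72,0.49,0.1075,false,1.34,0.47,0.2549,false
LOVASTATIN,compound,2.84,0.53,0.0127,true,1.78,0.18,0.006,true
METHOXYISOFLAVONE,compound,2.32,0.5,0.039,true,1.97,0.34,0.051,true
EDARAVONE,compound,3.86,0.39,0.0009,true,2.76,0.58,0.0197,true
CHLORMADINONE ACETATE,compound,3.12,0.57,0.0101,true,2.35,0.56,0.037,true
LOSARTAN,compound,2.38,0.63,0.0467,true,2.8,0.57,0.0532,true
FENAMISAL,compound,2.78,0.76,0.0726,false,1.38,0.22,0.1106,false
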