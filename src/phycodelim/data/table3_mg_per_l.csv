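strain,fatty_acid,mean,se,unit
VP336,14:0 Myristic,4.65,0.16,mg-per-L
VP336,16:0 Palmitic,86.0,3.06,mg-per-L
VP336,16:1n-9 Hypogeic,0.61,0.02,mg-per-L
VP336,16:1n-7 Palmitoleic,12.14,0.27,mg-per-L
VP336,"16:2n-6 7,10-Hexadecadienoic",1.01,0.04,mg-per-L
VP336,16:3n-3 Roughanic,41.10,0.96,mg-per-L
VP336,"16:4n-3 4,7,10,13-Hexadecatetraenoic",15.06,0.53,mg-per-L
VP336,18:0 Stearic,6.67,0.20,mg-per-L
VP336,18:1n-9 Oleic,6.61,0.11,mg-per-L
VP336,18:2n-6 Linoleic,17.32,0.33,mg-per-L
VP336,18:3n-3 α-Linolenic,179.44,3.51,mg-per-L
VP336,18:4n-3 Stearidonic,0.19,0.01,mg-per-L
VP336,20:0 Arachidic,0.37,0.01,mg-per-L
VP336,20:4n-6 Arachidonic,7.24,0.36,mg-per-L
VP336,20:5n-3 Eicosapentaenoic,3.24,0.05,mg-per-L
VP339,14:0 Myristic,2.78,0.11,mg-per-L
VP339,16:0 Palmitic,237.0,6.66,mg-per-L
VP339,16:1n-9 Hypogeic,5.11,0.13,mg-per-L
VP339,16:1n-7 Palmitoleic,43.51,0.71,mg-per-L
VP339,"16:2n-6 7,10-Hexadecadienoic",86.61,1.50,mg-per-L
VP339,16:3n-3 Roughanic,25.26,0.31,mg-per-L
VP339,"16:3n-6 4,7,10-Hexadecatrienoic",86.61,0.94,mg-per-L
VP339,"16:4n-3 4,7,10,13-Hexadecatetraenoic",299.49,9.77,mg-per-L
VP339,18:0 Stearic,5.34,0.09,mg-per-L
VP339,18:1n-9 Oleic,139.87,2.18,mg-per-L
VP339,18:2n-6 Linoleic,165.40,3.99,mg-per-L
VP339,18:3n-6 γ-Linolenic,1.89,0.03,mg-per-L
VP339,18:3n-3 α-Linolenic,572.85,11.66,mg-per-L
VP339,18:4n-3 Stearidonic,72.94,0.65,mg-per-L
VP339,20:0 Arachidic,0.56,0.02,mg-per-L
VP521,14:0 Myristic,0.97,0.03,mg-per-L
VP521,16:0 Palmitic,131.0,4.51,mg-per-L
VP521,16:1n-9 Hypogeic,3.89,0.05,mg-per-L
VP521,16:1n-7 Palmitoleic,12.50,0.28,mg-per-L
VP521,"16:2n-6 7,10-Hexadecadienoic",17.21,0.98,mg-per-L
VP521,16:3n-3 Roughanic,95.96,1.9,mg-per-L
VP521,18:0 Stearic,6.19,0.08,mg-per-L
VP521,18:1n-9 Oleic,33.30,0.83,mg-per-L
VP521,18:1n-7 Vaccenic,2.88,0.03,mg-per-L
VP521,18:2n-6 Linoleic,52.87,0.72,mg-per-L
VP521,18:3n-6 γ-Linolenic,0.30,0.01,mg-per-L
VP521,18:3n-3 α-Linolenic,237.65,5.17,mg-per-L
VP521,20:4n-6 Arachidonic,0.55,0.01,mg-per-L
VP449,14:0 Myristic,0.57,0.01,mg-per-L
VP449,16:0 Palmitic,74.57,1.78,mg-per-L
VP449,16:1n-9 Hypogeic,0.27,0.01,mg-per-L
VP449,16:1n-7 Palmitoleic,3.08,0.03,mg-per-L
VP449,"16:2n-6 7,10-Hexadecadienoic",9.19,0.53,mg-per-L
VP449,16:3n-3 Roughanic,18.44,0.44,mg-per-L
VP449,18:0 Stearic,6.96,0.05,mg-per-L
VP449,18:1n-9 Oleic,7.25,0.15,mg-per-L
VP449,18:1n-7 Vaccenic,1.63,0.05,mg-per-L
VP449,18:2n-6 Linoleic,51.90,0.64,mg-per-L
VP449,18:3n-6 γ-Linolenic,0.98,0.01,mg-per-L
VP449,18:3n-3 α-Linolenic,64.09,0.84,mg-per-L
VP449,20:4n-6 Arachidonic,0.42,0.01,mg-per-L
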