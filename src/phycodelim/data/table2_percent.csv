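strain,fatty_acid,mean,se,unit
VP336,14:0 Myristic,1.22,0.07,percent-of-total-FA
VP336,16:0 Palmitic,22.53,0.37,percent-of-total-FA
VP336,16:1n-9 Hypogeic,0.16,0.01,percent-of-total-FA
VP336,16:1n-7 Palmitoleic,3.18,0.09,percent-of-total-FA
VP336,"16:2n-6 7,10-Hexadecadienoic",0.26,0.02,percent-of-total-FA
VP336,16:3n-3 Roughanic,10.77,0.33,percent-of-total-FA
VP336,"16:4n-3 4,7,10,13-Hexadecatetraenoic",3.95,0.14,percent-of-total-FA
VP336,18:0 Stearic,1.74,0.07,percent-of-total-FA
VP336,18:1n-9 Oleic,1.73,0.05,percent-of-total-FA
VP336,18:2n-6 Linoleic,4.54,0.14,percent-of-total-FA
VP336,18:3n-3 α-Linolenic,47.02,0.76,percent-of-total-FA
VP336,18:4n-3 Stearidonic,0.05,0.01,percent-of-total-FA
VP336,20:0 Arachidic,0.10,0.01,percent-of-total-FA
VP336,20:4n-6 Arachidonic,1.90,0.06,percent-of-total-FA
VP336,20:5n-3 Eicosapentaenoic,0.85,0.20,percent-of-total-FA
VP339,14:0 Myristic,0.16,0.01,percent-of-total-FA
VP339,16:0 Palmitic,13.59,0.31,percent-of-total-FA
VP339,16:1n-9 Hypogeic,0.29,0.02,percent-of-total-FA
VP339,16:1n-7 Palmitoleic,2.49,0.09,percent-of-total-FA
VP339,"16:2n-6 7,10-Hexadecadienoic",4.95,0.14,percent-of-total-FA
VP339,16:3n-3 Roughanic,1.44,0.06,percent-of-total-FA
VP339,"16:3n-6 4,7,10-Hexadecatrienoic",4.96,0.14,percent-of-total-FA
VP339,"16:4n-3 4,7,10,13-Hexadecatetraenoic",17.16,0.57,percent-of-total-FA
VP339,18:0 Stearic,0.31,0.03,percent-of-total-FA
VP339,18:1n-9 Oleic,8.02,0.24,percent-of-total-FA
VP339,18:2n-6 Linoleic,9.48,0.12,percent-of-total-FA
VP339,18:3n-6 γ-Linolenic,0.11,0.02,percent-of-total-FA
VP339,18:3n-3 α-Linolenic,32.83,0.64,percent-of-total-FA
VP339,18:4n-3 Stearidonic,4.18,0.12,percent-of-total-FA
VP339,20:0 Arachidic,0.03,0.01,percent-of-total-FA
VP521,14:0 Myristic,0.16,0.02,percent-of-total-FA
VP521,16:0 Palmitic,22.01,0.59,percent-of-total-FA
VP521,16:1n-9 Hypogeic,0.65,0.04,percent-of-total-FA
VP521,16:1n-7 Palmitoleic,2.10,0.09,percent-of-total-FA
VP521,"16:2n-6 7,10-Hexadecadienoic",2.90,0.09,percent-of-total-FA
VP521,16:3n-3 Roughanic,16.12,0.39,percent-of-total-FA
VP521,18:0 Stearic,1.04,0.04,percent-of-total-FA
VP521,18:1n-9 Oleic,5.60,0.14,percent-of-total-FA
VP521,18:1n-7 Vaccenic,0.48,0.04,percent-of-total-FA
VP521,18:2n-6 Linoleic,8.88,0.24,percent-of-total-FA
VP521,18:3n-6 γ-Linolenic,0.05,0.01,percent-of-total-FA
VP521,18:3n-3 α-Linolenic,39.92,1.14,percent-of-total-FA
VP521,20:4n-6 Arachidonic,0.09,0.01,percent-of-total-FA
VP449,14:0 Myristic,0.24,0.01,percent-of-total-FA
VP449,16:0 Palmitic,31.16,1.03,percent-of-total-FA
VP449,16:1n-9 Hypogeic,0.11,0.02,percent-of-total-FA
VP449,16:1n-7 Palmitoleic,1.29,0.04,percent-of-total-FA
VP449,"16:2n-6 7,10-Hexadecadienoic",3.83,0.11,percent-of-total-FA
VP449,16:3n-3 Roughanic,7.70,0.21,percent-of-total-FA
VP449,18:0 Stearic,2.91,0.10,percent-of-total-FA
VP449,18:1n-9 Oleic,3.03,0.07,percent-of-total-FA
VP449,18:1n-7 Vaccenic,0.68,0.04,percent-of-total-FA
VP449,18:2n-6 Linoleic,21.69,0.34,percent-of-total-FA
VP449,18:3n-6 γ-Linolenic,0.41,0.02,percent-of-total-FA
VP449,18:3n-3 α-Linolenic,26.78,0.62,percent-of-total-FA
VP449,20:4n-6 Arachidonic,0.17,0.02,percent-of-total-FA
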