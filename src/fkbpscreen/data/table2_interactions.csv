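ligand,Tyr57,Asp68,Arg73,Phe77,Glu85,Val86,Trp90,Tyr113,Lys121,Phe130
Tacrolimus,-,-,Hb,Hb,Hb,-,-,H,-,-
Daphnetoxin,-,Hb,Pi,Hb,-,-,-,H,Hb,-
"20-O-(2'E,4'E-Decadienoyl)ingenol",-,Hb,Hb,Hb,-,Hb,Hb,H,H,-
Lythrancine II,H,H,H,Pi/Hb,-,-,-,H,-,Hb
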