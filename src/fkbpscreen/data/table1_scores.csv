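name,svm,mlr,bn,dock,is_control
Lathyranoic acid A,4.81,5.12,5.45,86.20,0
Daphnetoxin,5.09,8.89,7.46,84.88,0
Aurantiamide,4.89,6.42,5.43,83.89,0
"(6aR,11aR)-9,10-Dimethoxypterocarpan-3-O-beta-D-glucoside",5.00,8.33,5.56,83.50,0
Picrasidine M,5.10,7.51,5.65,69.60,0
12-O-Acetylphorbol-13-tigliate,4.91,7.40,6.15,68.88,0
"20-O-(2'E,4'E-Decadienoyl)ingenol",4.91,6.87,6.35,68.52,0
Howiinol A II,5.24,6.87,5.40,68.11,0
Moellendorffiline,5.15,6.64,5.98,63.24,0
Lythrancine II,5.03,8.92,6.74,62.03,0
Tacrolimus,5.11,6.25,5.33,58.10,1
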