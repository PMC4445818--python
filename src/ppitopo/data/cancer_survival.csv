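cancer,survival_pct,degree_entropy,cycle_basis,nominal_betti,best_betti
AML,23.6,2.16,108,107,95
Bladder,78.1,1.52,20,20,15
CML,55.2,2.11,115,114,101
Colorectal,63.6,1.63,58,51,41
Endometrial,68.6,1.6,45,45,35
Glioma,33.4,2.22,128,128,109
NSCL,18,2.23,75,50,37
Pancreatic,5.5,2,72,38,29
Renal,69.5,1.59,52,51,34
SCL,6.2,2.06,150,149,131
Thyroid,97.2,1.38,24,24,17
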