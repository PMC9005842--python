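step,covariate,lower,upper,sex,units
folate >= 4.0,folate,4.0,,,ng/mL
vitamin B12 180-914,vitb12,180,914,,pg/mL
ALT in range,alt,7,40,0,U/L
ALT in range,alt,9,50,1,U/L
AST in range,ast,13,35,0,U/L
AST in range,ast,15,40,1,U/L
creatinine in range,cr,45,84,0,μmol/L
creatinine in range,cr,59,104,1,μmol/L
urea 2.78-7.14,urea,2.78,7.14,,mmol/L
TSH 0.380-4.340,tsh,0.380,4.340,,μIU/L
FT3 1.80-4.10,ft3,1.80,4.10,,pg/mL
FT4 0.81-1.89,ft4,0.81,1.89,,ng/dL
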