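steps,loss_formula,provenance
RO1',C3H6O3,ring-opening H shift at a non-reducing hexose; neutral loss 90
RO2',C3H6O3,alternative ring-opening H shift; neutral loss 90
"c0',3'",C4H8O4,direct cross-ring cleavage; neutral loss 120
RO1'>m2'_3',CH2O,follow-up hydrogen migration; neutral loss 30
RO1'>m4'_5',C2H4O2,follow-up hydrogen migration; neutral loss 60
RO2'>m5'_6',C4H8O4,follow-up hydrogen migration; neutral loss 120
RO1'>m2'_3'>m3'_4'>c2',C4H8O4,multi-step route to neutral loss 120
RO2'>m5'_4'>c2',C4H8O4,multi-step route to neutral loss 120
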