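species,step,site,barrier_kJ_mol,ordering,sentinel_gt300,provenance
Hex,RO,reducing,200,4,False,upper bound; ring opening via O5-C1 cleavage is reported below 200 kJ/mol
Hex,m1_2,reducing,165,2,False,1.2-hydrogen shift after ring opening (printed TS energy)
Hex,m1_3,reducing,163,1,False,1.3-hydrogen shift; outside the shift set used for enumeration; kept for completeness
Hex,m1_4,reducing,203,6,False,printed TS energy
Hex,m1_5,reducing,195,3,False,printed TS energy
Hex,m1_6,reducing,201,5,False,printed TS energy
Hex,concerted_3cc_a,any,,,True,concerted triple C-C cleavage without ring opening; above 300 kJ/mol
Hex,concerted_3cc_b,any,,,True,concerted triple C-C cleavage without ring opening; above 300 kJ/mol
Hex-OMe,RO1',non_reducing,231,1,False,printed TS energy (H shift to O5 with ring opening)
Hex-OMe,"c0',3'",non_reducing,232,2,False,printed TS energy (direct cross-ring)
Hex-OMe,RO2',non_reducing,257,3,False,printed TS energy
Hex-OMe,RO3',non_reducing,,,True,above 300 kJ/mol
Hex-OMe,RO4',non_reducing,,,True,above 300 kJ/mol
Man1-2Man,c2,reducing,152,1,False,printed TS energy
Man1-2Man,m1_4,reducing,161,2,False,value assigned from the reported triple (161/172/190) by sentence order
Man1-2Man,m1_5,reducing,172,3,False,value assigned from the reported triple (161/172/190) by sentence order
Man1-2Man,m1_6,reducing,190,4,False,value assigned from the reported triple (161/172/190) by sentence order
Man1-2Man,RO1',non_reducing,,,False,shown graphically only; well above reducing-end barriers
Man1-2Man,RO2',non_reducing,,,False,shown graphically only; well above reducing-end barriers
Man1-2Man,"c0',3'",non_reducing,,,False,shown graphically only; well above reducing-end barriers
Man1-3Man,m1_5,reducing,,1,False,ordinal only: lowest TS energy of the four shifts
Man1-3Man,m1_2,reducing,,2,False,ordinal only: second lowest
Man1-3Man,m1_6,reducing,,3,False,ordinal only: third lowest
Man1-3Man,m1_4,reducing,,4,False,ordinal only: highest
Man1-3Man,RO1',non_reducing,218,1,False,printed TS energy
Man1-3Man,"c0',3'",non_reducing,225,2,False,printed TS energy
Man1-3Man,RO2',non_reducing,254,3,False,printed TS energy
Man1-4Man,c2,reducing,,1,False,ordinal only: reported lowest TS energy
Man1-4Man,m1_2,reducing,,2,False,ordinal only: reported relatively low
Man1-4Man,m1_5,reducing,178,3,False,printed TS energy
Man1-4Man,m1_6,reducing,178,3,False,printed TS energy (equal to m1_5)
Man1-4Man,RO1',non_reducing,226,1,False,printed TS energy
Man1-4Man,"c0',3'",non_reducing,240,2,False,printed TS energy
Man1-4Man,RO2',non_reducing,247,3,False,printed TS energy
GlcNAc1-2Man,c2,reducing,156,1,False,printed TS energy
GlcNAc1-2Man,m1_6,reducing,163,2,False,printed TS energy
GlcNAc1-2Man,m1_5,reducing,168,3,False,printed TS energy
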