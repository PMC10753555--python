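# Crystalline-phase targets -dfH(cr, 298.15 K), kJ mol^-1, for coumarins with
# published experimental values, plus curator-authored structural descriptors.
# h_count/o_count are atom counts; radical_1 is the substituent nearer the
# carbonyl (ring positions 3/4), radical_2 the benzo-ring substituent
# (positions 5-8); names resolve through the configurable encoding table.
# The descriptor assignment (slotting and encoding) is interpretive: the
# published record states the regressor meaning but not the numeric coding.
compound_id,h_count,o_count,radical_1,radical_2,target_minus_dfH_cr
coumarin,6,2,none,none,259.9
7H4MC,8,3,CH3,OH,540.8
6M4MC,10,3,CH3,OCH3,488
6HC,6,3,none,OH,466.2
7HC,6,3,none,OH,471.1
3HC,6,3,OH,none,459.6
4HC,6,3,OH,none,479.9
7MC,8,3,none,OCH3,428.9
7M4MC,10,3,CH3,OCH3,488.5
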