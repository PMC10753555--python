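# Updated Benson group coefficients for esters/coumarins, kJ mol^-1,
# contributions to -dfH(g, 298.15 K) (published regression update).
# Labels: CB = aromatic carbon, CD = doubly-bonded carbon, CT = triply-bonded
# carbon, CO = carbonyl carbon; rsc = ring-strain correction; "radical n" and
# "correction O-/M-/P-" are positional correction terms; "group ..." are
# family indicators. H0 is the regression intercept.
group,value
H0,34.86
CO-(CD)(O),11.32
CO-(C)(O),25.79
CO-(O)(CB),24.17
O-(H)(CO),0
O-(C)(CB),-12.55
O-(H)(CB),86.57
CD-(H)(CO),3.71
CD-(C)(CO),7.61
CB-(CO)(CB)2,36.31
CB-(O)(CB)2,102.58
C-(CO)(C)3,-202.02
C-(H)(CO)(C)2,-23.98
C-(H)2(CO)(C),14.58
C-(H)3(O),82.38
C-(H)3(CD),11.32
C-(H)3(C),82.40
C-(H)3(CB),41.51
C-(H)2(C)2,20.33
C-(H)(C)3,-9.91
CD-(H)2,16.60
CB-(H)(CB)2,-11.82
CB-(C)(CB)2,-6.02
C-(H)2(C)(CB),-20.83
CH3(tert),2.46
CH3(qua),0
CO-(C)(CO),81.83
CO-(C)(CB),35.00
O-(CD)(CO),0
O-(CB)(CO),28.56
CD-(O)(H),0
C-(H)2(CO)2,127.97
C-(H)3(CO),75.37
C-(H)2(CO)(CD),-3.29
C-(H)2(CO)(CT),0
C-(O)(C)3,-54.98
C-(H)(O)(C)2,-8.64
C-(H)2(O)(C),32.42
O-(CO)(O),0
CD-(H)(C),6.12
CD-(H)(CD),0
C-(H)2(C)(CD),5.70
CT-(C),0
CB-(CB)3,22.86
CB-(H)(CO)(CB),-12.55
CB-(CO)2(CB),0
rsc,-17.59
radical 1,-4.11
radical 2,-1.86
radical 3,0.68
correction O-,-10.37
correction M-,-4.82
correction P-,-4.09
group aromatic,-57.16
group coumarin,22.86
group ester,34.30
O-(C)(CO),158.54
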