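contribution,water_model,salt_mM,printed
-dG_p_S,TIP3P,81,-7.61(2)
-dG_p_S,TIP3P,177,-9.00(4)
-dG_p_S,TIP3P,450,-8.73(5)
-dG_p_S,TIP4P-D,81,-7.25(4)
-dG_p_S,TIP4P-D,177,-9.28(6)
-dG_p_S,TIP4P-D,450,-9.2(1)
-dG_n_S,TIP3P,81,-3.81(1)
-dG_n_S,TIP3P,177,-1.84(2)
-dG_n_S,TIP3P,450,-1.70(1)
-dG_n_S,TIP4P-D,81,-2.25(5)
-dG_n_S,TIP4P-D,177,-2.10(3)
-dG_n_S,TIP4P-D,450,-1.87(3)
-dG_o_S,TIP3P,81,-2.49(2)
-dG_o_S,TIP3P,177,-2.19(2)
-dG_o_S,TIP3P,450,-1.38(1)
-dG_o_S,TIP4P-D,81,-2.24(4)
-dG_o_S,TIP4P-D,177,-1.36(2)
-dG_o_S,TIP4P-D,450,-2.21(3)
-dG_a_S,TIP3P,81,-0.85(1)
-dG_a_S,TIP3P,177,-0.34(1)
-dG_a_S,TIP3P,450,-0.40(1)
-dG_a_S,TIP4P-D,81,-0.93(1)
-dG_a_S,TIP4P-D,177,-0.44(1)
-dG_a_S,TIP4P-D,450,-0.44(1)
sep_term,TIP3P,81,-28.3(2)
sep_term,TIP3P,177,-26.0(3)
sep_term,TIP3P,450,-23.9(3)
sep_term,TIP4P-D,81,-24.6(3)
sep_term,TIP4P-D,177,-21.7(3)
sep_term,TIP4P-D,450,-17.5(3)
dG_o_B,TIP3P,81,6.81
dG_o_B,TIP3P,177,6.81
dG_o_B,TIP3P,450,6.81
dG_o_B,TIP4P-D,81,6.81
dG_o_B,TIP4P-D,177,6.81
dG_o_B,TIP4P-D,450,6.81
dG_p_B,TIP3P,81,13.1(1)
dG_p_B,TIP3P,177,12.7(2)
dG_p_B,TIP3P,450,11.8(1)
dG_p_B,TIP4P-D,81,14.1(2)
dG_p_B,TIP4P-D,177,16.4(2)
dG_p_B,TIP4P-D,450,15.7(2)
dG_n_B,TIP3P,81,3.20(3)
dG_n_B,TIP3P,177,3.42(5)
dG_n_B,TIP3P,450,2.05(4)
dG_n_B,TIP4P-D,81,1.85(3)
dG_n_B,TIP4P-D,177,1.69(4)
dG_n_B,TIP4P-D,450,1.89(3)
dG_b,TIP3P,81,-20.0(4)
dG_b,TIP3P,177,-16.5(6)
dG_b,TIP3P,450,-15.5(5)
dG_b,TIP4P-D,81,-14.5(6)
dG_b,TIP4P-D,177,-10.1(6)
dG_b,TIP4P-D,450,-6.8(6)
ddG_p_BS,TIP3P,81,5.5(1)
ddG_p_BS,TIP3P,177,3.7(2)
ddG_p_BS,TIP3P,450,3.1(1)
ddG_p_BS,TIP4P-D,81,6.9(2)
ddG_p_BS,TIP4P-D,177,7.1(2)
ddG_p_BS,TIP4P-D,450,6.5(2)
ddG_n_BS,TIP3P,81,-0.62(3)
ddG_n_BS,TIP3P,177,1.58(5)
ddG_n_BS,TIP3P,450,0.35(4)
ddG_n_BS,TIP4P-D,81,-0.4(1)
ddG_n_BS,TIP4P-D,177,-0.4(1)
ddG_n_BS,TIP4P-D,450,0.02(4)
ddG_o_BS,TIP3P,81,4.32(1)
ddG_o_BS,TIP3P,177,4.62(1)
ddG_o_BS,TIP3P,450,5.43(1)
ddG_o_BS,TIP4P-D,81,4.57(1)
ddG_o_BS,TIP4P-D,177,5.45(1)
ddG_o_BS,TIP4P-D,450,4.6(1)
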