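enzyme,name,symbol,value,unit
ADH,K_a,K11,180,uM
ADH,K_b,K12,17000,uM
ADH,K_p,K13,800,uM
ADH,K_q,K14,100,uM
ADH,K_ia,K15,270,uM
ADH,K_ib,K16,90000,uM
ADH,K_ip,K17,1100,uM
ADH,K_iq,K18,31,uM
ADH,kcat_f,V11,40,1/s
ADH,kcat_r,V12,340,1/s
ADH,K_eq,Keq1,22,1e-12 M
ALD,K_a,K21,20,uM
ALD,K_b,K22,9,uM
ALD,K_ia,K25,70,uM
ALD,K_iq,K28,100,uM
ALD,kcat_f,V21,1,1/s
LDH,K_a,K31,24,uM
LDH,K_b,K32,120,uM
LDH,K_p,K33,6000,uM
LDH,K_q,K34,100,uM
LDH,K_ia,K35,8,uM
LDH,K_ib,K36,130,uM
LDH,K_ip,K37,130000,uM
LDH,K_iq,K38,100,uM
LDH,kcat_f,V31,550,1/s
LDH,kcat_r,V32,60,1/s
LDH,K_eq,Keq3,3.8,1e-12 M
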