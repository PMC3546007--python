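strategy,implant_type,n_implants,n_fused_levels,uiv,liv,rod_thoracic_deg,rod_lumbar_deg
S1,screw,10,10,T4,L2,30,30
S2,screw,10,9,T4,L1,20,45
S3,screw,13,11,T3,L2,20,30
S4,screw,13,15,T2,L4,20,45
S5,screw,12,10,T4,L2,20,30
S6,screw,12,12,T3,L3,20,30
S7,screw,12,14,T2,L3,30,30
S8,screw,11,10,T4,L2,20,45
S9,screw,8,8,T5,L1,20,45
S10,screw,12,14,T3,L4,30,45
S11,screw,11,11,T4,L3,30,45
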