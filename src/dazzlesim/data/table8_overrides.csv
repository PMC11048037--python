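scene_id,D_um,P_mW_cm2,U_deg,level,all_covered
S-1,70.23,1.537,1.62,II,0
S-2,54.15,1.537,1.52,II,0
S-3,45.67,1.537,1.39,III,0
S-4,23.63,1.537,0.88,III,0
S-5,11.04,1.537,0.53,III,0
S-6,9.69,1.537,0.47,II,0
S-7,18.69,1.537,0.76,II,0
S-8,54.35,0.249,2.81,III,0
S-9,,0.063,3.54,I,1
S-10,18.69,1.537,0.76,I,0
S-11,18.98,1.537,0.77,I,0
S-12,19.23,1.537,0.79,II,0
S-13,18.82,1.537,0.77,II,0
S-14,19.54,1.537,0.8,III,0
S-15,19.97,1.537,0.85,III,0
S-16,70.23,1.537,1.94,II,0
S-17,54.15,1.537,1.79,II,0
S-18,45.67,1.537,1.42,III,0
S-19,23.63,1.537,1.33,III,0
S-20,11.04,1.537,0.69,III,0
S-21,9.69,1.537,0.51,II,0
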