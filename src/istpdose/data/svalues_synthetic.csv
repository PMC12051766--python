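# SYNTHETIC S-value matrix for tests and examples. These are NOT OpenDose
# values: magnitudes are chosen so that, with the synthetic cohort's typical
# organ TIAs, absorbed doses land in the few-Gy (kidney), sub-Gy (spleen) and
# centi-Gy (liver) ranges expected for Lu-177 PSMA therapy. Self-dose terms
# dominate; cross-organ terms are orders of magnitude smaller.
source,target,s_value,units
left_kidney,left_kidney,5.0e-4,Gy_per_MBq_h
left_kidney,right_kidney,5.0e-7,Gy_per_MBq_h
left_kidney,liver,8.0e-7,Gy_per_MBq_h
left_kidney,spleen,2.0e-6,Gy_per_MBq_h
right_kidney,left_kidney,5.0e-7,Gy_per_MBq_h
right_kidney,right_kidney,5.0e-4,Gy_per_MBq_h
right_kidney,liver,1.0e-6,Gy_per_MBq_h
right_kidney,spleen,1.0e-6,Gy_per_MBq_h
liver,left_kidney,8.0e-7,Gy_per_MBq_h
liver,right_kidney,1.0e-6,Gy_per_MBq_h
liver,liver,4.0e-5,Gy_per_MBq_h
liver,spleen,1.5e-6,Gy_per_MBq_h
spleen,left_kidney,2.0e-6,Gy_per_MBq_h
spleen,right_kidney,1.0e-6,Gy_per_MBq_h
spleen,liver,1.5e-6,Gy_per_MBq_h
spleen,spleen,1.5e-3,Gy_per_MBq_h
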