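# SYNTHETIC population prior for the fixed uptake term (A2, lambda2) of the
# biexponential model. These are NOT clinical values: the published
# population table is not publicly available, so this fixture is calibrated
# only so that organ uptake peaks before 2 h post-injection at typical
# washout parameters.
organ,A2_MBq,lambda2_per_h
left_kidney,40.0,2.0
right_kidney,40.0,2.0
liver,30.0,1.5
spleen,10.0,2.5
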