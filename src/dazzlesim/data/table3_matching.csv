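lighting,ambient_luminance,trial,volunteer,age,matched,note
bright,235.0,1,NO.1,25,1,
bright,235.0,2,NO.2,33,1,
bright,235.0,3,NO.3,35,0,nearsighted; stronger stimulus with glasses
bright,235.0,4,NO.4,42,1,
bright,235.0,5,NO.5,48,1,
dim,0.025,1,NO.1,25,1,
dim,0.025,2,NO.2,33,1,
dim,0.025,3,NO.3,35,1,
dim,0.025,4,NO.4,42,1,
dim,0.025,5,NO.5,48,1,
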