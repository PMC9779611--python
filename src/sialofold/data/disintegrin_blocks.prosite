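ID   DISINTEGRIN_RGD; PATTERN.
PA   R-G-D.
//
ID   DISINTEGRIN_KGD; PATTERN.
PA   K-G-D.
//
ID   DISINTEGRIN_KTS; PATTERN.
PA   K-T-S.
//
ID   DISINTEGRIN_RTS; PATTERN.
PA   R-T-S.
//
ID   DISINTEGRIN_RED; PATTERN.
PA   R-E-D.
//
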