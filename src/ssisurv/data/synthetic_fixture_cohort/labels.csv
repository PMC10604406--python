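surgery_id,deep_ssi,ssi_onset_day
FX00000,false,
FX00001,false,
FX00002,false,
FX00003,false,
FX00004,true,15
FX00005,true,29
FX00006,false,
FX00007,false,
FX00008,false,
FX00009,false,
FX00010,false,
FX00011,false,
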