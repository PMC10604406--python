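surgery_id,patient_id,surgery_date,specialty,department,is_index
FX00000,P-FX00000,2019-02-02,colorectal surgery,surgery,true
FX00001,P-FX00001,2019-06-13,colorectal surgery,surgery,true
FX00002,P-FX00002,2019-02-23,colorectal surgery,surgery,true
FX00003,P-FX00003,2019-08-26,colorectal surgery,surgery,true
FX00004,P-FX00004,2019-09-29,colorectal surgery,surgery,true
FX00005,P-FX00005,2019-01-18,colorectal surgery,surgery,true
FX00006,P-FX00006,2019-02-26,colorectal surgery,surgery,true
FX00007,P-FX00007,2019-11-11,colorectal surgery,surgery,true
FX00008,P-FX00008,2019-07-27,colorectal surgery,surgery,true
FX00009,P-FX00009,2019-03-23,colorectal surgery,surgery,true
FX00010,P-FX00010,2019-12-25,colorectal surgery,surgery,true
FX00011,P-FX00011,2019-10-02,colorectal surgery,surgery,true
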