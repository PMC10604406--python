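patient_id,admit_date,discharge_date,department,died_in_hospital
P-FX00000,2019-01-30,2019-02-05,surgery,false
P-FX00000,2019-03-08,2019-03-11,medicine,false
P-FX00001,2019-06-12,2019-07-02,surgery,true
P-FX00002,2019-02-22,2019-03-09,surgery,true
P-FX00003,2019-08-23,2019-08-31,surgery,false
P-FX00004,2019-09-26,2019-10-04,surgery,false
P-FX00005,2019-01-16,2019-01-21,surgery,false
P-FX00005,2019-02-27,2019-03-06,surgery,false
P-FX00006,2019-02-25,2019-03-05,surgery,false
P-FX00007,2019-11-10,2019-11-30,surgery,false
P-FX00008,2019-07-24,2019-08-05,surgery,false
P-FX00009,2019-03-20,2019-04-28,surgery,true
P-FX00010,2019-12-23,2019-12-30,surgery,false
P-FX00011,2019-10-02,2019-10-05,surgery,false
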