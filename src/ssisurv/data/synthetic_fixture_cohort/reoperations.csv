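patient_id,operation_date,specialty
P-FX00001,2019-07-05,orthopaedics
P-FX00002,2019-03-03,colorectal surgery
P-FX00004,2019-10-17,colorectal surgery
P-FX00005,2019-02-20,orthopaedics
P-FX00006,2019-04-09,colorectal surgery
P-FX00007,2019-11-28,colorectal surgery
P-FX00008,2019-08-14,colorectal surgery
P-FX00009,2019-03-31,colorectal surgery
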