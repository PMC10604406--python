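patient_id,order_date,modality
P-FX00000,2019-03-12,ultrasound
P-FX00002,2019-03-08,CT
P-FX00002,2019-03-19,MRI
P-FX00004,2019-10-22,CT
P-FX00005,2019-01-22,CT
P-FX00007,2019-11-20,X-ray
P-FX00008,2019-08-15,CT
P-FX00010,2020-01-13,CT
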