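patient_id,administration_date,atc_code
P-FX00000,2019-02-02,J01DC02
P-FX00002,2019-02-23,J01DC02
P-FX00002,2019-03-29,J01DH02
P-FX00002,2019-03-30,J01DH02
P-FX00002,2019-03-31,J01DH02
P-FX00002,2019-04-01,J01DH02
P-FX00002,2019-04-02,J01DH02
P-FX00002,2019-04-03,J01DH02
P-FX00003,2019-08-26,J01DC02
P-FX00004,2019-10-15,J01MA02
P-FX00004,2019-10-16,J01MA02
P-FX00004,2019-10-17,J01MA02
P-FX00004,2019-10-18,J01MA02
P-FX00004,2019-10-19,J01MA02
P-FX00004,2019-10-20,J01MA02
P-FX00005,2019-01-18,J01DC02
P-FX00005,2019-02-13,J01MA02
P-FX00005,2019-02-14,J01MA02
P-FX00005,2019-02-15,J01MA02
P-FX00005,2019-02-16,J01MA02
P-FX00006,2019-03-30,J01MA02
P-FX00007,2019-11-11,J01DC02
P-FX00008,2019-07-27,J01DC02
P-FX00010,2019-12-25,J01DC02
P-FX00011,2019-10-02,J01DC02
P-FX00011,2019-10-15,J01MA02
P-FX00011,2019-10-16,J01MA02
P-FX00011,2019-10-17,J01MA02
P-FX00011,2019-10-18,J01MA02
P-FX00011,2019-10-19,J01MA02
P-FX00011,2019-10-20,J01MA02
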