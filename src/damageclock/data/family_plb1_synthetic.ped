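id	father	mother	generation	at_risk	founder_carrier	married_in
I-1	0	0	1	0	1	0
I-2	0	0	1	0	0	1
II-1	I-1	I-2	2	1	0	0
II-2	I-1	I-2	2	1	0	0
II-3	I-1	I-2	2	1	0	0
II-4	I-1	I-2	2	1	0	0
II-5	I-1	I-2	2	1	0	0
II-6	I-1	I-2	2	1	0	0
II-7	I-1	I-2	2	1	0	0
II-8	I-1	I-2	2	1	0	0
II-9	I-1	I-2	2	1	0	0
II-10	I-1	I-2	2	1	0	0
II-11	I-1	I-2	2	1	0	0
II-12	I-1	I-2	2	1	0	0
II-1s	0	0	2	0	0	1
III-1	II-1	II-1s	3	1	0	0
III-2	II-1	II-1s	3	1	0	0
III-3	II-1	II-1s	3	1	0	0
III-4	II-1	II-1s	3	1	0	0
II-3s	0	0	2	0	0	1
III-5	II-3	II-3s	3	1	0	0
III-6	II-3	II-3s	3	1	0	0
III-7	II-3	II-3s	3	1	0	0
III-8	II-3	II-3s	3	1	0	0
II-5s	0	0	2	0	0	1
III-9	II-5	II-5s	3	1	0	0
III-10	II-5	II-5s	3	1	0	0
III-11	II-5	II-5s	3	1	0	0
II-8s	0	0	2	0	0	1
III-12	II-8	II-8s	3	1	0	0
III-13	II-8	II-8s	3	1	0	0
III-14	II-8	II-8s	3	1	0	0
II-10s	0	0	2	0	0	1
III-15	II-10	II-10s	3	1	0	0
III-16	II-10	II-10s	3	1	0	0
III-17	II-10	II-10s	3	1	0	0
II-12s	0	0	2	0	0	1
III-18	II-12	II-12s	3	1	0	0
III-19	II-12	II-12s	3	1	0	0
III-1s	0	0	3	0	0	1
IV-1	III-1	III-1s	4	1	0	0
IV-2	III-1	III-1s	4	1	0	0
IV-3	III-1	III-1s	4	1	0	0
III-5s	0	0	3	0	0	1
IV-4	III-5	III-5s	4	1	0	0
IV-5	III-5	III-5s	4	1	0	0
III-9s	0	0	3	0	0	1
IV-6	III-9	III-9s	4	1	0	0
IV-7	III-9	III-9s	4	1	0	0
III-13s	0	0	3	0	0	1
IV-8	III-13	III-13s	4	1	0	0
IV-9	III-13	III-13s	4	1	0	0
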