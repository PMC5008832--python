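patient_id,group,age_first,age_last,years_fup,qpcr_cyr61_t0,qpcr_taz_t0,ihc_cyr61_t0,ihc_taz_t0,qpcr_cyr61_t1,qpcr_taz_t1,ihc_cyr61_t1,ihc_taz_t1
11,nonP-BE,64,81,17,Low,Low,++,+,Low,Low,+,+
13,nonP-BE,62,65,3,Low,Low,++,+,Low,Low,+,+
14,nonP-BE,65,75,10,Low,Low,++,++,Low,Low,+,+
21,nonP-BE,66,77,11,Low,Low,+,-,Low,Low,++,-
22,nonP-BE,67,74,7,Low,Low,+,+,Low,Low,+,+
25,nonP-BE,32,42,10,High,High,++,-,Low,Low,+,-
26,nonP-BE,64,76,12,Low,High,+,-,Low,Low,++,+
27,nonP-BE,42,52,10,Low,Low,++,-,Low,Low,++,+
28,nonP-BE,52,63,11,Low,Low,+++,-,Low,Low,+,-
29,nonP-BE,51,54,3,Low,Low,+,+,Low,Low,+,-
2,P-BE,71,72,1,Low,High,+++,+,Low,High,+++,+
3,P-BE,46,59,13,High,High,++,++,Low,High,+,++
4,P-BE,50,54,4,Low,High,+++,+,Low,Low,++,+
5,P-BE,51,53,2,Low,High,++,++,Low,Low,+,++
6,P-BE,45,48,3,High,High,+++,+,High,High,++,-
17,P-BE,62,67,5,High,High,+++,++,High,High,+,+
18,P-BE,48,54,6,High,High,+,-,High,High,+++,+
19,P-BE,68,69,1,Low,Low,+++,++,High,Low,+,++
20,P-BE,51,57,6,High,High,+,++,Low,Low,++,++
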