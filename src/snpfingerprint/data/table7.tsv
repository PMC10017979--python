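Marker	Yateliben(REF/ALT)	Bainong 2(REF/ALT)	Weizi(REF/ALT)
Marker 1	A/G	A/A	A/G
Marker 2	G/G	G/G	G/G
Marker 3	A/G	G/G	A/A
Marker 4	A/A	A/G	A/G
Marker 5	A/A	G/G	A/G
Marker 6	T/T	T/T	T/T
Marker 7	G/G	A/A	G/G
Marker 8	C/C	T/C	C/C
Marker 9	A/A	A/G	A/A
Marker 10	A/G	A/A	A/A
Marker 11	T/G	T/G	T/T
Marker 12	G/G	G/G	A/A
Marker 13	T/T	T/T	T/T
Marker 14	A/A	G/G	G/G
Marker 15	G/G	T/G	T/G
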