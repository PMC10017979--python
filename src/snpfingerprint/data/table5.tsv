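Marker	Yujin 1(REF/ALT)	Yujin 2(REF/ALT)	Mixian Damaohua(REF/ALT)	Telei 1(REF/ALT)
Marker 1	G/G	A/G	A/A	A/A
Marker 2	G/G	G/G	G/G	A/A
Marker 3	R/A	A/A	R/G	G/G
Marker 4	A/A	G/G	A/A	R/G
Marker 5	A/A	G/G	A/A	G/G
Marker 6	M/A	M/A	M/A	A/C
Marker 7	G/G	M/A	G/G	A/A
Marker 8	C/C	G/G	C/C	Y/C
Marker 9	A/A	C/A	A/A	R/G
Marker 10	G/R	G/G	R/G	R/A
Marker 11	G/G	K/G	K/G	K/G
Marker 12	G/G	A/A	G/G	G/G
Marker 13	R/A	G/G	M/C	G/G
Marker 14	Y/C	T/T	Y/C	Y/C
Marker 15	T/T	C/C	T/T	Y/C
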