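Number	YJ01(REF/ALT)	YJ02(REF/ALT)	YJ03(REF/ALT)	YJ04(REF/ALT)	YJ05(REF/ALT)	YJ06(REF/ALT)	YJ07(REF/ALT)	YJ08(REF/ALT)	YJ09(REF/ALT)	YJ10(REF/ALT)
Marker1	A/G	A/G	A/G	A/G	A/G	A/G	A/G	A/G	A/G	A/G
Marker2	G/G	G/G	G/G	G/G	G/G	G/G	G/G	G/G	G/G	G/G
Marker3	A/A	A/A	A/A	A/A	A/A	A/A	A/A	A/A	A/A	A/A
Marker4	A/A	A/A	A/A	A/A	A/A	A/A	A/A	A/A	A/A	A/A
Marker5	A/A	A/A	A/A	A/A	A/A	A/A	A/A	A/A	A/A	A/A
Marker6	T/T	T/T	T/T	T/T	T/T	T/T	T/T	T/T	T/T	T/T
Marker7	G/G	G/G	G/G	G/G	G/G	G/G	G/G	G/G	G/G	G/G
Marker8	C/C	C/C	C/C	C/C	C/C	C/C	C/C	C/C	C/C	C/C
Marker9	A/A	A/A	A/A	A/A	A/A	A/A	A/A	A/A	A/A	A/A
Marker10	A/G	A/G	A/G	A/A	A/A	A/A	A/G	A/A	A/A	A/A
Marker11	T/G	T/G	T/G	T/G	T/G	T/G	T/G	T/G	T/G	T/G
Marker12	G/G	G/G	G/G	G/G	G/G	G/G	G/G	G/G	G/G	G/G
Marker13	T/T	T/T	T/T	T/T	T/T	T/T	T/T	T/T	T/T	T/T
Marker14	A/A	A/A	A/A	A/A	A/A	A/A	A/A	A/A	A/A	A/A
Marker15	G/G	G/G	G/G	G/G	G/G	G/G	G/G	G/G	G/G	G/G
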