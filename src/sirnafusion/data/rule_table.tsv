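# Majority-compiled positional design-rule codes for the siRNA guide strand,
# positions 1-19 (5'->3'). code = +1: nucleotide at that position prefers high
# efficacy; -1: prefers low efficacy; 0: no published rule.
# Compiled from 12 published rule sets by majority vote; providers listed per cell.
# Known caveat: the source's prose worked example argues (9, U) should resolve to +1
# by majority, but its printed compiled table assigns -1; this file follows the
# printed table. See docs/methods.md.
position	nucleotide	code	providers
1	A	-1	Ui-Tei,Amarzguioui,Takasaki,Svetlana,Matveeva
1	C	1	Ui-Tei,Amarzguioui,Jagla1,Jagla2,Jagla3,Matveeva
1	G	1	Ui-Tei,Amarzguioui,Takasaki,Svetlana,Jagla1,Jagla2,Jagla3,Matveeva,Jiang
1	U	-1	Ui-Tei,Amarzguioui,Takasaki,Svetlana,Matveeva,Jiang
2	A	-1	Amarzguioui
2	C	0
2	G	1	Svetlana,Jiang
2	U	-1	Amarzguioui,Matveeva
3	A	1	Reynolds
3	C	-1	Matveeva
3	G	1	Svetlana,Jiang
3	U	-1	Amarzguioui,Svetlana,Jiang
4	A	0
4	C	-1	Svetlana
4	G	0
4	U	1	Matveeva
5	A	1	Jagla4
5	C	0
5	G	0
5	U	1	Jagla4
6	A	1	Amarzguioui,Takasaki,Svetlana,Jagla4,Matveeva,Jiang
6	C	-1	Hsieh,Takasaki,Svetlana,Matveeva,Jiang
6	G	-1	Svetlana,Svetlana
6	U	1	Svetlana,Jagla4,Matveeva,Jiang
7	A	1	Svetlana,Matveeva,Jiang
7	C	-1	Svetlana,Matveeva,Jiang
7	G	1	Takasaki
7	U	-1	Takasaki
8	A	1	Takasaki
8	C	0
8	G	-1	Takasaki
8	U	0
9	A	0
9	C	0
9	G	-1	Takasaki,Matveeva
9	U	-1	Jagla1,Jiang
10	A	1	Jagla1
10	C	1	Jagla2
10	G	1	Jagla2
10	U	1	Reynolds,Svetlana,Jagla1,Matveeva,Jiang
11	A	0
11	C	1	Hsieh,Jagla3
11	G	1	Hsieh,Jagla3
11	U	0
12	A	1	Matveeva
12	C	0
12	G	-1	Matveeva
12	U	0
13	A	1	Svetlana,Matveeva,Jiang
13	C	-1	Svetlana,Jiang
13	G	-1	Reynolds,Svetlana,Jiang
13	U	1	Svetlana,Matveeva,Jiang
14	A	0
14	C	-1	Svetlana,Jiang
14	G	0
14	U	0
15	A	1	Svetlana,Jiang
15	C	-1	Matveeva
15	G	0
15	U	-1	Svetlana,Jiang
16	A	0
16	C	0
16	G	1	Hsieh
16	U	1	Matveeva
17	A	1	Amarzguioui,Svetlana,Matveeva,Jiang
17	C	0
17	G	-1	Matveeva
17	U	1	Amarzguioui
18	A	1	Amarzguioui,Svetlana,Matveeva,Jiang
18	C	-1	Svetlana,Matveeva,Jiang
18	G	-1	Matveeva
18	U	1	Svetlana
19	A	1	Ui-Tei,Amarzguioui,Svetlana,Jagla1,Jagla2,Jagla4,Matveeva,Jiang
19	C	-1	Reynolds,Ui-Tei,Matveeva,Jiang
19	G	-1	Reynolds,Ui-Tei,Amarzguioui,Hsieh,Takasaki,Svetlana,Matveeva,Jiang
19	U	1	Ui-Tei,Amarzguioui,Hsieh,Svetlana,Jagla1,Jagla2,Jagla4,Matveeva,Jiang
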