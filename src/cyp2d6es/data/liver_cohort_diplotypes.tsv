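diplotype	count_aa	count_ea
*1/*1	5	20
*1/*2	19	23
*1/*4	4	9
*1/*5	3	0
*1/*6	1	0
*1/*9	1	0
*1/*10	2	3
*1/*17	10	2
*1/*29	4	1
*1/*41	8	3
*2/*2	4	8
*2/*3	2	9
*2/*5	2	1
*2/*9	0	1
*2/*10	4	2
*2/*17	2	1
*2/*29	3	2
*2/*41	2	5
*3/*9	0	1
*4/*10	1	2
*4/*17	0	6
*4/*4	0	2
*4/*5	0	1
*4/*6	0	1
*4/*9	5	0
*4/*29	5	0
*4/*41	1	0
*5/*17	1	0
*5/*41	1	1
*6/*10	0	1
*6/*29	1	0
*9/*41	0	1
*10/*10	0	1
*10/*17	2	1
*10/*41	0	2
*17/*17	1	1
*17/*29	3	0
*29/*29	2	1
*41/*41	1	2
*1/*1x2	2	1
*1/*2x2	1	0
*1/*4x2	3	0
*1/*17x2	1	0
*1/*29x2	3	0
*2/*4x2	1	1
*2/*1x2	1	0
*2x2/*2x2	2	0
*2x2/*4x3	1	0
*4/*1x2	1	0
*4/*4x2	1	0
*4/*29x2	1	0
*9/*29x2	0	1
*10/*2x2	1	0
*10/*4x2	1	1
*29/*2x2	0	1
*41/*4x2	1	0
*2x2/*4x2	0	1
*1x4/*2x5	0	1
unlisted	2	0
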