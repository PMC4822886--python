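position	label	codon	kind	category
1	reverse	CGG	function	CAT3
2	1	AGC	digit	CAT1
3	2	TGA	digit	CAT1
4	3	GAC	digit	CAT1
5	4	CGA	digit	CAT1
6	5	ACG	digit	CAT1
7	6	TAG	digit	CAT1
8	7	GCT	digit	CAT1
9	8	TCG	digit	CAT1
10	9	GCA	digit	CAT1
11	0	CTG	digit	CAT1
12	.	TTA	character	CAT3
13	,	GAA	character	CAT3
14	e	GAT	character	CAT1
15	a	ATC	character	CAT1
16	:	AAC	character	CAT3
17	;	AAT	character	CAT3
18	r	TCA	character	CAT1
19	i	CGT	character	CAT1
20	o	ATG	character	CAT1
21	p	CGC	character	CAT2
22	m	GTG	character	CAT2
23	t	GTA	character	CAT1
24	n	ACT	character	CAT1
25	h	TGT	character	CAT2
26	!	CTT	character	CAT3
27	?	TTG	character	CAT3
28	'	ATT	character	CAT3
29	g	CAC	character	CAT2
30	s	TGC	character	CAT1
31	l	CAT	character	CAT1
32	b	TCT	character	CAT2
33	f	GCG	character	CAT2
34	y	GAG	character	CAT2
35	w	CTC	character	CAT2
36	"	CCA	character	CAT3
37	k	TTC	character	CAT3
38	x	AGA	character	CAT2
39	-	TCC	character	CAT3
40	&	ACC	character	CAT3
41	(	TGG	character	CAT3
42	)	AGG	character	CAT3
43	/	GGA	character	CAT3
44	@	AAG	character	CAT3
45	z	ATA	character	CAT2
46	v	GTT	character	CAT3
47	j	TAT	character	CAT2
48	c	GTC	character	CAT1
49	q	ACA	character	CAT2
50	u	CAG	character	CAT1
51	d	TAC	character	CAT1
52	#	TAA	character	CAT3
53	$	CAA	character	CAT3
54	start	AAA	function	CAT3
55	shift	CCC	function	CAT3
56	end	GGG	function	CAT3
57	forward	TTT	function	CAT3
58	space1	AGT	function	CAT1
59	space2	CTA	function	CAT1
60	%	GGC	character	CAT3
61	+	GGT	character	CAT3
62	=	CCT	character	CAT3
63	*	GCC	character	CAT3
64	_	CCG	character	CAT3
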