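marker_id	published_n_units	sample_id	tissue	n_units	algorithm_identified
C6R16	16	1	normal	15	1
C6R16	16	1	tumor	15	1
C6R16	16	2	normal	16	1
C6R16	16	2	tumor	15	1
C6R16	16	3	normal	15	1
C6R16	16	3	tumor	15	1
C6R16	16	4	normal	15	1
C6R16	16	4	tumor	16	1
C6R16	16	5	normal	15	1
C6R16	16	5	tumor	15	1
C6R16	16	6	normal	16	1
C6R16	16	6	tumor	15	1
C6R16	16	7	normal	15	1
C6R16	16	7	tumor	15	1
C8R17	17	1	normal	17	1
C8R17	17	1	tumor	17	1
C8R17	17	2	normal	17	1
C8R17	17	2	tumor	17	1
C8R17	17	3	normal	17	1
C8R17	17	3	tumor	17	1
C8R17	17	4	normal	17	1
C8R17	17	4	tumor	17	1
C8R17	17	5	normal	17	1
C8R17	17	5	tumor	18	1
C8R17	17	6	normal	17	1
C8R17	17	6	tumor	17	1
C8R17	17	7	normal	17	1
C8R17	17	7	tumor	16	1
C9R17	17	1	normal	17	1
C9R17	17	1	tumor	17	1
C9R17	17	2	normal	17	1
C9R17	17	2	tumor	17	1
C9R17	17	3	normal	17	1
C9R17	17	3	tumor	17	1
C9R17	17	4	normal	16	1
C9R17	17	4	tumor	16	1
C9R17	17	5	normal	17	1
C9R17	17	5	tumor	17	1
C9R17	17	6	normal	17	1
C9R17	17	6	tumor	17	1
C9R17	17	7	normal	17	1
C9R17	17	7	tumor	17	1
C10R18	18	1	normal	17	1
C10R18	18	1	tumor	18	1
C10R18	18	2	normal	18	1
C10R18	18	2	tumor	17	1
C10R18	18	3	normal	17	1
C10R18	18	3	tumor	17	1
C10R18	18	4	normal	17	1
C10R18	18	4	tumor	17	1
C10R18	18	5	normal	17	1
C10R18	18	5	tumor	17	1
C10R18	18	6	normal	17	1
C10R18	18	6	tumor	17	1
C10R18	18	7	normal	18	1
C10R18	18	7	tumor	18	1
C14R15	15	1	normal	15	1
C14R15	15	1	tumor	15	1
C14R15	15	2	normal	15	1
C14R15	15	2	tumor	15	1
C14R15	15	3	normal	15	1
C14R15	15	3	tumor	15	1
C14R15	15	4	normal	15	1
C14R15	15	4	tumor	15	1
C14R15	15	5	normal	15	1
C14R15	15	5	tumor	15	1
C14R15	15	6	normal	16	1
C14R15	15	6	tumor	15	1
C14R15	15	7	normal	15	1
C14R15	15	7	tumor	15	1
C14R16	16	1	normal	15	1
C14R16	16	1	tumor	16	1
C14R16	16	2	normal	16	1
C14R16	16	2	tumor	15	1
C14R16	16	3	normal	15	1
C14R16	16	3	tumor	15	1
C14R16	16	4	normal	16	1
C14R16	16	4	tumor	16	1
C14R16	16	5	normal	16	1
C14R16	16	5	tumor	15	1
C14R16	16	6	normal	15	1
C14R16	16	6	tumor	14	1
C14R16	16	7	normal	15	1
C14R16	16	7	tumor	16	1
C19R16	16	1	normal	16	1
C19R16	16	1	tumor	16	1
C19R16	16	2	normal	16	1
C19R16	16	2	tumor	16	1
C19R16	16	3	normal	16	1
C19R16	16	3	tumor	16	1
C19R16	16	4	normal	16	1
C19R16	16	4	tumor	16	1
C19R16	16	5	normal	16	1
C19R16	16	5	tumor	16	1
C19R16	16	6	normal	16	1
C19R16	16	6	tumor	16	1
C19R16	16	7	tumor	16	1
Ch18R14.1	14	1	normal	14	0
Ch18R14.1	14	1	tumor	14	0
Ch18R14.1	14	2	normal	14	0
Ch18R14.1	14	2	tumor	14	0
Ch18R14.1	14	3	normal	14	0
Ch18R14.1	14	3	tumor	14	0
Ch18R14.1	14	4	normal	14	0
Ch18R14.1	14	4	tumor	14	0
Ch18R14.1	14	5	normal	14	0
Ch18R14.1	14	5	tumor	14	0
Ch18R14.1	14	6	normal	14	0
Ch18R14.1	14	6	tumor	14	0
Ch18R14.1	14	7	normal	14	0
Ch18R14.1	14	7	tumor	14	0
Ch18R14.2	14	1	normal	14	0
Ch18R14.2	14	1	tumor	14	0
Ch18R14.2	14	2	normal	14	0
Ch18R14.2	14	2	tumor	14	0
Ch18R14.2	14	3	normal	14	0
Ch18R14.2	14	3	tumor	14	0
Ch18R14.2	14	4	normal	14	0
Ch18R14.2	14	4	tumor	14	0
Ch18R14.2	14	5	normal	14	0
Ch18R14.2	14	5	tumor	14	0
Ch18R14.2	14	6	normal	14	0
Ch18R14.2	14	6	tumor	14	0
Ch18R14.2	14	7	normal	14	0
Ch18R14.2	14	7	tumor	14	0
C10R18	18	P1	parental	18	1
C10R18	18	P2	parental	18	1
C10R18	18	P3	parental	18	1
C10R18	18	P4	parental	18	1
C10R18	18	P5	parental	18	1
C10R18	18	P6	parental	18	1
C10R18	18	P7	parental	18	1
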