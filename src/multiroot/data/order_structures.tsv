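# order-structures v1 samples=2000000 draws=200 seed=1
shape	kind	i	j
caterpillar	eq	3	6
caterpillar	eq	4	9
caterpillar	eq	5	12
caterpillar	eq	7	8
caterpillar	eq	7	10
caterpillar	eq	7	11
caterpillar	eq	7	13
caterpillar	eq	7	14
caterpillar	eq	8	10
caterpillar	eq	8	11
caterpillar	eq	8	13
caterpillar	eq	8	14
caterpillar	eq	10	11
caterpillar	eq	10	13
caterpillar	eq	10	14
caterpillar	eq	11	13
caterpillar	eq	11	14
caterpillar	eq	13	14
caterpillar	gt	0	1
caterpillar	gt	0	3
caterpillar	gt	0	4
caterpillar	gt	0	6
caterpillar	gt	0	7
caterpillar	gt	0	8
caterpillar	gt	0	9
caterpillar	gt	0	10
caterpillar	gt	0	11
caterpillar	gt	0	13
caterpillar	gt	0	14
caterpillar	gt	1	4
caterpillar	gt	1	7
caterpillar	gt	1	8
caterpillar	gt	1	9
caterpillar	gt	1	10
caterpillar	gt	1	11
caterpillar	gt	1	13
caterpillar	gt	1	14
caterpillar	gt	2	1
caterpillar	gt	2	3
caterpillar	gt	2	4
caterpillar	gt	2	5
caterpillar	gt	2	6
caterpillar	gt	2	7
caterpillar	gt	2	8
caterpillar	gt	2	9
caterpillar	gt	2	10
caterpillar	gt	2	11
caterpillar	gt	2	12
caterpillar	gt	2	13
caterpillar	gt	2	14
caterpillar	gt	3	4
caterpillar	gt	3	7
caterpillar	gt	3	8
caterpillar	gt	3	9
caterpillar	gt	3	10
caterpillar	gt	3	11
caterpillar	gt	3	13
caterpillar	gt	3	14
caterpillar	gt	4	7
caterpillar	gt	4	8
caterpillar	gt	4	10
caterpillar	gt	4	11
caterpillar	gt	4	13
caterpillar	gt	4	14
caterpillar	gt	5	4
caterpillar	gt	5	7
caterpillar	gt	5	8
caterpillar	gt	5	9
caterpillar	gt	5	10
caterpillar	gt	5	11
caterpillar	gt	5	13
caterpillar	gt	5	14
caterpillar	gt	6	4
caterpillar	gt	6	7
caterpillar	gt	6	8
caterpillar	gt	6	9
caterpillar	gt	6	10
caterpillar	gt	6	11
caterpillar	gt	6	13
caterpillar	gt	6	14
caterpillar	gt	9	7
caterpillar	gt	9	8
caterpillar	gt	9	10
caterpillar	gt	9	11
caterpillar	gt	9	13
caterpillar	gt	9	14
caterpillar	gt	12	4
caterpillar	gt	12	7
caterpillar	gt	12	8
caterpillar	gt	12	9
caterpillar	gt	12	10
caterpillar	gt	12	11
caterpillar	gt	12	13
caterpillar	gt	12	14
balanced	eq	0	1
balanced	eq	3	4
balanced	eq	3	6
balanced	eq	3	9
balanced	eq	4	6
balanced	eq	4	9
balanced	eq	5	12
balanced	eq	6	9
balanced	eq	7	8
balanced	eq	7	10
balanced	eq	7	11
balanced	eq	7	13
balanced	eq	7	14
balanced	eq	8	10
balanced	eq	8	11
balanced	eq	8	13
balanced	eq	8	14
balanced	eq	10	11
balanced	eq	10	13
balanced	eq	10	14
balanced	eq	11	13
balanced	eq	11	14
balanced	eq	13	14
balanced	gt	0	3
balanced	gt	0	4
balanced	gt	0	6
balanced	gt	0	7
balanced	gt	0	8
balanced	gt	0	9
balanced	gt	0	10
balanced	gt	0	11
balanced	gt	0	13
balanced	gt	0	14
balanced	gt	1	3
balanced	gt	1	4
balanced	gt	1	6
balanced	gt	1	7
balanced	gt	1	8
balanced	gt	1	9
balanced	gt	1	10
balanced	gt	1	11
balanced	gt	1	13
balanced	gt	1	14
balanced	gt	2	0
balanced	gt	2	1
balanced	gt	2	3
balanced	gt	2	4
balanced	gt	2	5
balanced	gt	2	6
balanced	gt	2	7
balanced	gt	2	8
balanced	gt	2	9
balanced	gt	2	10
balanced	gt	2	11
balanced	gt	2	12
balanced	gt	2	13
balanced	gt	2	14
balanced	gt	3	7
balanced	gt	3	8
balanced	gt	3	10
balanced	gt	3	11
balanced	gt	3	13
balanced	gt	3	14
balanced	gt	4	7
balanced	gt	4	8
balanced	gt	4	10
balanced	gt	4	11
balanced	gt	4	13
balanced	gt	4	14
balanced	gt	5	3
balanced	gt	5	4
balanced	gt	5	6
balanced	gt	5	7
balanced	gt	5	8
balanced	gt	5	9
balanced	gt	5	10
balanced	gt	5	11
balanced	gt	5	13
balanced	gt	5	14
balanced	gt	6	7
balanced	gt	6	8
balanced	gt	6	10
balanced	gt	6	11
balanced	gt	6	13
balanced	gt	6	14
balanced	gt	9	7
balanced	gt	9	8
balanced	gt	9	10
balanced	gt	9	11
balanced	gt	9	13
balanced	gt	9	14
balanced	gt	12	3
balanced	gt	12	4
balanced	gt	12	6
balanced	gt	12	7
balanced	gt	12	8
balanced	gt	12	9
balanced	gt	12	10
balanced	gt	12	11
balanced	gt	12	13
balanced	gt	12	14
pseudo_caterpillar	eq	1	2
pseudo_caterpillar	eq	4	5
pseudo_caterpillar	eq	4	7
pseudo_caterpillar	eq	4	8
pseudo_caterpillar	eq	4	9
pseudo_caterpillar	eq	4	10
pseudo_caterpillar	eq	4	12
pseudo_caterpillar	eq	4	13
pseudo_caterpillar	eq	5	7
pseudo_caterpillar	eq	5	8
pseudo_caterpillar	eq	5	9
pseudo_caterpillar	eq	5	10
pseudo_caterpillar	eq	5	12
pseudo_caterpillar	eq	5	13
pseudo_caterpillar	eq	7	8
pseudo_caterpillar	eq	7	9
pseudo_caterpillar	eq	7	10
pseudo_caterpillar	eq	7	12
pseudo_caterpillar	eq	7	13
pseudo_caterpillar	eq	8	9
pseudo_caterpillar	eq	8	10
pseudo_caterpillar	eq	8	12
pseudo_caterpillar	eq	8	13
pseudo_caterpillar	eq	9	10
pseudo_caterpillar	eq	9	12
pseudo_caterpillar	eq	9	13
pseudo_caterpillar	eq	10	12
pseudo_caterpillar	eq	10	13
pseudo_caterpillar	eq	11	14
pseudo_caterpillar	eq	12	13
pseudo_caterpillar	gt	0	1
pseudo_caterpillar	gt	0	2
pseudo_caterpillar	gt	0	3
pseudo_caterpillar	gt	0	4
pseudo_caterpillar	gt	0	5
pseudo_caterpillar	gt	0	6
pseudo_caterpillar	gt	0	7
pseudo_caterpillar	gt	0	8
pseudo_caterpillar	gt	0	9
pseudo_caterpillar	gt	0	10
pseudo_caterpillar	gt	0	11
pseudo_caterpillar	gt	0	12
pseudo_caterpillar	gt	0	13
pseudo_caterpillar	gt	0	14
pseudo_caterpillar	gt	1	4
pseudo_caterpillar	gt	1	5
pseudo_caterpillar	gt	1	7
pseudo_caterpillar	gt	1	8
pseudo_caterpillar	gt	1	9
pseudo_caterpillar	gt	1	10
pseudo_caterpillar	gt	1	12
pseudo_caterpillar	gt	1	13
pseudo_caterpillar	gt	2	4
pseudo_caterpillar	gt	2	5
pseudo_caterpillar	gt	2	7
pseudo_caterpillar	gt	2	8
pseudo_caterpillar	gt	2	9
pseudo_caterpillar	gt	2	10
pseudo_caterpillar	gt	2	12
pseudo_caterpillar	gt	2	13
pseudo_caterpillar	gt	3	4
pseudo_caterpillar	gt	3	5
pseudo_caterpillar	gt	3	7
pseudo_caterpillar	gt	3	8
pseudo_caterpillar	gt	3	9
pseudo_caterpillar	gt	3	10
pseudo_caterpillar	gt	3	12
pseudo_caterpillar	gt	3	13
pseudo_caterpillar	gt	6	4
pseudo_caterpillar	gt	6	5
pseudo_caterpillar	gt	6	7
pseudo_caterpillar	gt	6	8
pseudo_caterpillar	gt	6	9
pseudo_caterpillar	gt	6	10
pseudo_caterpillar	gt	6	12
pseudo_caterpillar	gt	6	13
pseudo_caterpillar	gt	11	4
pseudo_caterpillar	gt	11	5
pseudo_caterpillar	gt	11	7
pseudo_caterpillar	gt	11	8
pseudo_caterpillar	gt	11	9
pseudo_caterpillar	gt	11	10
pseudo_caterpillar	gt	11	12
pseudo_caterpillar	gt	11	13
pseudo_caterpillar	gt	14	4
pseudo_caterpillar	gt	14	5
pseudo_caterpillar	gt	14	7
pseudo_caterpillar	gt	14	8
pseudo_caterpillar	gt	14	9
pseudo_caterpillar	gt	14	10
pseudo_caterpillar	gt	14	12
pseudo_caterpillar	gt	14	13
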