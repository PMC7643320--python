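animal_id	late_puberty	testis	prostate	kidney	obesity	tumor	multiple_disease	total_disease
PS1	-	-	-	-	-	-	-	0
PS2	-	-	-	-	-	-	-	0
PS3	-	+	-	-	-	-	-	1
PS4	-	+	-	-	-	-	-	1
PS5	-	-	-	-	-	-	-	0
PS6	-	-	-	-	-	-	-	0
PS7	-	-	-	-	-	-	-	0
PS8	-	-	-	-	-	-	-	0
PS9	-	+	-	-	-	-	-	1
PS10	-	-	-	-	-	-	-	0
PS11	-	-	-	-	-	-	-	0
PS12	-	-	-	-	-	-	-	0
PS13	-	-	-	-	-	-	-	0
PS14	-	+	-	+	-	-	+	2
PS15	-	-	-	-	-	-	-	0
PS16	-	-	-	+	-	-	-	1
PS17	-	n/a	+	-	-	-	-	1
PS18	-	-	-	-	-	-	-	0
PS19	-	-	+	-	-	-	-	1
PS20	-	+	+	+	+	-	+	4
PS21	-	-	-	-	-	-	-	0
PS22	-	+	+	-	-	-	+	2
PS23	-	-	-	+	-	-	-	1
PS24	-	-	-	-	-	-	-	0
PS25	-	-	-	+	-	-	-	1
PS26	-	-	+	-	-	-	-	1
PS27	+	+	-	+	+	-	+	4
PS28	-	-	-	+	-	-	-	1
PS29	-	+	-	-	+	-	+	2
PS30	-	+	-	+	-	-	+	2
PS31	-	-	-	+	-	-	-	1
PS32	+	+	-	-	-	-	+	2
PS33	+	-	-	-	-	-	-	1
PS34	+	-	-	+	-	-	+	2
PS35	n/a	+	+	-	-	-	+	2
PS36	n/a	+	-	+	-	-	+	2
PS37	n/a	+	+	+	-	-	+	3
PS38	n/a	+	-	+	-	-	+	2
PS39	-	-	-	-	-	+	-	1
PS40	-	-	+	-	-	-	-	1
PS41	-	-	-	+	-	-	-	1
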