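contig	precursor_id	strand	start	end	seed_similarity	mature_id	tissue	sex	direction	fold_change
NODE_173406	mir-99a	-	9625	9682	nbr-mir-99a	mir-99a-5p	gonad	F	down	-1.23
NODE_173406	novel_13044	+	9626	9684	gmo-mir-100b-5p	novel_13044-3p	brain	M	up	1.38
NODE_615561	novel_37864	-	499	563	abu-mir-27c	novel_37864-5p	brain	F	up	2.78
NODE_615561	novel_37864	-	499	563	abu-mir-27c	novel_37864-3p	brain	F	up	2.49
NODE_615561	novel_37866	-	714	773	abu-mir-23c	novel_37866-5p	brain	F	up	2.68
NODE_615561	novel_37866	-	714	773	abu-mir-23c	novel_37866-3p	brain	F	up	2.51
NODE_65503	novel_5423	-	4439	4498	ccr-mir-217	novel_5423-5p	gonad	F	down	-2.16
NODE_65503	novel_5423	-	4439	4498	ccr-mir-217	novel_5423-3p	gonad	F	down	-1.76
NODE_65503	novel_5425	-	5012	5075	ccr-mir-216a	novel_5425-5p	gonad	F	down	-1.11
NODE_65503	novel_5427	-	5708	5768	ccr-mir-216b	novel_5427-3p	gonad	F	down	-2.19
NODE_65503	novel_5427	-	5708	5768	ccr-mir-216b	novel_5427-5p	gonad	F	down	-1.70
NODE_65503	novel_5427	-	5708	5768	ccr-mir-216b	novel_5427-5p	muscle	F	up	2.50
NODE_843581	mir-194	-	58381	58436	ccr-mir-194	mir-194-3p	muscle	M	down	-2.33
NODE_843581	mir-192	-	58185	58246	ccr-mir-192	mir-192-3p	muscle	M	down	-2.67
NODE_91705	mir-212-2	-	2623	2690	dre-mir-212-2	mir-212-2-5p	gonad	F	down	-1.89
NODE_91705	novel_7483	-	4415	4473	gmo-mir-2184	novel_7483-5p	brain	F	up	1.27
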