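id	species	exon2	exon3	exon4	exon5	exon10	exon23	exon31	exon32	exon33_coding	tss_truncation	printed_mw_kda	accession	partial
h-v1	human	+	+	+	+	+	-	+	+	-		131.5	NP_002456	-
h-v2	human	+	+	+	+	+	-	-	+	-		129	NP_996555	-
h-v3	human	+	+	-	-	+	+	-	+	-		128	NP_996556	-
h-v4	human	+	+	-	-	+	-	-	+	-		126.5	NP_996557	-
h-v5	human	+	+	-	-	+	+	+	-	+		131.5	NP_001241647	-
h-v6	human	+	+	-	-	+	-	+	+	-		129	NP_001241648	-
h-v7	human	-	+	-	-	+	-	+	+	-		128	NP_001241649	-
h-v8	human	+	+	-	-	-	-	+	+	-		127	NP_001241650	-
h-v9	human	-	-	-	-	+	-	+	+	-		126	NP_001241651	-
h-v10	human	-	-	+	-	+	-	-	-	+		128	NP_001241652	-
h-v002	human	+	-	-	-	+	-	+	+	-		127.5	ENSP00000447362	-
h-v012	human	-	-	-	-	+	-	-	+	-	7	115.5	EAW97667.1	-
h-v013	human	+	+	+	-	+	+	-	+	-		129.5	ENSP00000447660	-
h-v202	human	+	+	-	-	+	+	+	+	-		131	EAW97664.1	-
m-v4	mouse	+	+	-	-	+	-	-	+	-		126	NP_780627	-
m-v002	mouse	+	-	-	-	+	-	+	+	-		126.5	NP_001239301	-
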