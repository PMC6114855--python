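animal_id	early_puberty	late_puberty	testis	prostate	kidney	tumor	lean	obese
14V1-3-1-3	-	-	+	+	-	-	-	+
14V1-3-1-4	-	-	-	-	+	-	-	-
14V1-3-4-5	-	-	-	+	+	-	-	-
14V1-3-4-6	-	-	-	-	+	-	+	-
14V1-3-4-7	-	-	+	-	-	-	-	-
14V1-3-4-8	-	-				-
14V1-3-4-9	-	-				-
14V1-3-4-10	-	-				-
14V1-3-4-11	-	-				-
14V1-3-4-12	-	-				-
14V2-3-3-7	-	-	-	-	+	-	-	+
14V2-3-3-8	-	-	+	+	-	-	-	-
14V2-3-3-9	-	-				-
14V2-3-3-10	-	-				-
14V3-3-2-5	-	-	-	+	-	-	-	+
14V3-3-2-7	-	-				-
14V3-3-2-6	-	-	-	-	-	-	-	-
14V3-3-2-8	-	-				-
14V3-3-8-6	-	-	-	-	+	-	+	-
14V3-3-8-7	-	-	+	-	+	-	-	-
14V3-3-8-8	-	-				-
14V6-3-6-6	-	-	-	-	+	-	-	-
14V6-3-6-7	-	-	+	-	+	-	-	-
14V6-3-6-8	-	-				-
14V6-3-7-2	-	-	+	-	+	-	+	-
14V6-3-7-3	-	-				-
15V14-3-14-6	-	-	-	+	-	-	-	-
15V14-3-14-7	-	-	+	-	+	-	-	-
15V14-3-14-8	-	-	+	-	-	-	-	+
15V14-3-14-9	-	-	-	+	-	-	-	+
15V14-3-14-10	-	-				-
15V14-3-14-11	-	-				-
15V14-3-14-12	-	-				-
15V14-3-14-13	-	-				-
15V14-3-15-10	-	-	+	-	-	-	-	-
15V14-3-15-11	-	-	+	+	+	-	-	-
15V14-3-15-7	-	-	+	+	-	-	-	+
15V14-3-15-8			+	+	-	-	-	-
15V14-3-15-9	-	-	-	+	-	-	-	-
15V15-3-17-9			+	+		-	-	-
15V15-3-19-8	-	-				-
15V15-3-19-7	-	-				-
15V25-3-20-5	-	-	-	-	-	-	-	-
15V25-3-20-6	-	-	-	+	+	-	-	+
15V25-3-20-7	-	-	-	+	+	-	-	-
15V25-3-20-9	-	+				+
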