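# Apicomplexan genera detected per tick DNA sample and PCR/purification method.
# Codes: N unclassified Apicomplexa; A Amoebogregarina; G Gregarina;
# Cr Cryptosporidium; T Theileria; EU unclassified Eugregarinorida;
# Co unclassified Colpodellidae.  "-" = none detected.
tick_id	control	PNA-AMPure	PNA-SizeSelect	LNA-AMPure	LNA-SizeSelect	UNM
66	-	-	-	-	-	-
210	-	-	-	-	-	Cr
258	-	-	-	-	-	-
467	-	-	-	-	-	T
932	-	-	-	-	-	-
933	-	-	-	-	-	-
2592	-	G, A	-	A	-	G, A
2874	N	G, N	G, N	G, N	G, N	G, EU, N, Co
2876	-	-	-	-	-	-
3148	-	-	-	-	-	-
3149	-	-	-	-	-	-
3332	-	G	G	G	G	G
3611	-	-	-	-	-	-
3620	-	-	-	-	-	-
3631	-	-	-	-	-	-
3643	-	-	-	-	-	-
3648	-	-	-	-	-	-
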