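##gff-version 3
molecule_1	potato_mt	tRNA	17220	17294	.	-	.	gene_id=trnP-UGG-1
molecule_1	potato_mt	tRNA	17545	17618	.	-	.	gene_id=trnF-GAA
molecule_1	potato_mt	tRNA	17981	18068	.	-	.	gene_id=trnS-GCU
molecule_1	potato_mt	tRNA	37458	37531	.	-	.	gene_id=trnMf-CAU
molecule_1	potato_mt	tRNA	55772	55854	.	-	.	gene_id=trnY-GUA
molecule_1	potato_mt	tRNA	56390	56461	.	-	.	gene_id=trnN-GUU-1;plastid_like=true
molecule_1	potato_mt	tRNA	58606	58676	.	-	.	gene_id=trnC-GCA-1
molecule_1	potato_mt	tRNA	171005	171076	.	+	.	gene_id=trnC-GCA-2;plastid_like=true
molecule_1	potato_mt	tRNA	173488	173561	.	+	.	gene_id=trnI-CAU-1;plastid_like=true
molecule_1	potato_mt	tRNA	189363	189435	.	-	.	gene_id=trnMe-CAU;plastid_like=true
molecule_1	potato_mt	tRNA	201326	201397	.	+	.	gene_id=trnG-GCC
molecule_1	potato_mt	tRNA	204702	204773	.	+	.	gene_id=trnQ-UUG
molecule_1	potato_mt	tRNA	260636	260709	.	+	.	gene_id=trnI-CAU-2
molecule_2	potato_mt	tRNA	28511	28582	.	+	.	gene_id=trnN-GUU-2;plastid_like=true
molecule_2	potato_mt	tRNA	35798	35884	.	-	.	gene_id=trnS-UGA
molecule_2	potato_mt	tRNA	43141	43214	.	+	.	gene_id=trnD-GUC;plastid_like=true
molecule_2	potato_mt	tRNA	43901	43987	.	+	.	gene_id=trnS-GGA;plastid_like=true
molecule_2	potato_mt	tRNA	64733	64804	.	-	.	gene_id=trnV-GAC;plastid_like=true
molecule_3	potato_mt	tRNA	7326	7398	.	-	.	gene_id=trnK-UUU
molecule_3	potato_mt	tRNA	23306	23377	.	-	.	gene_id=trnE-UUC
molecule_3	potato_mt	tRNA	40411	40484	.	-	.	gene_id=trnW-CCA;plastid_like=true
molecule_3	potato_mt	tRNA	40642	40715	.	-	.	gene_id=trnP-UGG-2
molecule_3	potato_mt	tRNA	45897	45971	.	-	.	gene_id=trnH-GUG;plastid_like=true
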