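probe_id,exposures,chromosome,position,gene,gene_region,island_relation
cg14798382,GWG,chr19,"16,629,806",CHERP; C19orf44,3'UTR,N_Shore
cg19242268,GWG & BMI,chr20,"62,688,573",TCEA2,1st Exon; 5'UTR,Island
cg21516291,GWG,chr20,"44,979,100",SLC35C2,Body,OpenSea
cg08461903,GWG,chr21,"45,884,825",,,S_Shore
cg17040807,BMI,chr17,"74,533,282",CYGB,Body,Island
cg26552621,BMI,chr19,"1,271,019",C19orf23; CIRBP,TSS 1500; Body,S_Shore
cg04457572,BMI,chr10,"73,303,234",CDH23,Body,OpenSea
cg06457011,BMI,chr20,"39,767,490",PLCG1,Body,S_Shore
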