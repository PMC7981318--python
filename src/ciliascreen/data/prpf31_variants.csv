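gene,transcript,cdna_change,protein_change,category,n_reported_cases,align_gvgd,sift,polyphen2,splice_impact,domain_location,maf,same_codon_known_variant,functional_call
PRPF31,NM_015629.4,c.149C>T,p.Thr50Ile,test_variant,0,unavailable,unavailable,unavailable,unavailable,PRPF6-binding interface,,False,indeterminate
PRPF31,NM_015629.4,c.413C>A,p.Thr138Lys,test_variant,0,unavailable,unavailable,unavailable,unavailable,,,False,PS3
PRPF31,NM_015629.4,c.634A>G,p.Met212Val,test_variant,0,unavailable,unavailable,unavailable,unavailable,,,False,indeterminate
PRPF31,NM_015629.4,c.736G>A,p.Ala246Thr,test_variant,0,unavailable,unavailable,unavailable,unavailable,,,False,BS3
PRPF31,NM_015629.4,c.1297G>A,p.Val433Ile,test_variant,0,unavailable,unavailable,unavailable,unavailable,,,False,indeterminate
PRPF31,NM_015629.4,c.564G>A,p.Glu188Glu,benign_control,0,unavailable,unavailable,unavailable,unavailable,,0.022400955,False,
PRPF31,NM_015629.4,c.735T>C,p.Pro245Pro,benign_control,0,unavailable,unavailable,unavailable,unavailable,,0.0855321567,False,
PRPF31,NM_015629.4,c.1467T>C,p.Val489Val,benign_control,0,unavailable,unavailable,unavailable,unavailable,,0.0821705509,False,
PRPF31,NM_015629.4,c.341T>A,p.Ile114Asn,pathogenic_control,1,unavailable,unavailable,unavailable,unavailable,,,False,PS3
PRPF31,NM_015629.4,c.581C>A,p.Ala194Glu,pathogenic_control,1,unavailable,unavailable,unavailable,unavailable,,,False,PS3
PRPF31,NM_015629.4,c.646G>C,p.Ala216Pro,pathogenic_control,1,unavailable,unavailable,unavailable,unavailable,,,False,PS3
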