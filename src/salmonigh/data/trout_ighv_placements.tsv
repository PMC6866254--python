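# Rainbow trout IGHV gene placement census: number of V genes upstream of the
# functional tau cluster versus between the tau cluster and the mu/delta cluster,
# per chromosome. 129 genes total: chr13 (locus A) 44 + 5 = 49; chr12 (locus B)
# 70 + 10 = 80.
chromosome	locus_id	region	n_genes
chr13	A	upstream_of_tau_cluster	44
chr13	A	between_tau_and_mu_clusters	5
chr12	B	upstream_of_tau_cluster	70
chr12	B	between_tau_and_mu_clusters	10
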