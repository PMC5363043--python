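dataset	tissue	geo_accession	n_arrays	n_modules
Milano	diffuse skin	GSE9285	75	39
Pendergrass	diffuse skin	GSE32413	89	38
Hinchcliff	diffuse skin	GSE45485;GSE59785	165	62
LSSc	limited skin	GSE76806	24	39
UCL	limited skin	GSE76807	15	98
Christmann	lung	GSE76808	18	56
Bostwick	lung	GSE48149	62	54
ESO	esophagus	GSE68698	33	71
PBMC	pbmc	GSE19617	54	38
Risbano	pbmc	GSE22356	38	54
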