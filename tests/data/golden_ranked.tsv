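# condock 0.1.0
# command: predict
# config: background=uniform cutoff=3.5 dialect=swissdock source=grades
# config_sha256: 765a55995589
# input: receptor.pdb sha256=2cc604f8df4a
# input: poses_swissdock.pdb sha256=a42af0411df2
# input: grades.txt sha256=464393ee2191
pose_id	energy_score	conservation_score	condock_score	rank	n_site_residues	site_residues	reason
c5.0	-3350.3750	0.888889	-2978.1111	1	4	A:25;A:33;A:41;A:48	
c4.0	-3564.9366	0.222222	-792.2081	2	1	A:19	
c7.0	-3502.2365	0.222222	-778.2748	3	1	A:54	
c0.0	-3423.3811	0.222222	-760.7514	4	1	A:54	
c9.0	-3421.3429	0.222222	-760.2984	5	1	A:14	
c10.0	-3381.1280	0.222222	-751.3618	6	1	A:28	
c3.0	-3371.7970	0.222222	-749.2882	7	2	A:36;A:44	
c6.0	-3363.7766	0.222222	-747.5059	8	1	A:14	
c2.0	-3336.9734	0.222222	-741.5496	9	1	A:39	
c1.0	-3316.4209	0.222222	-736.9824	10	2	A:38;A:46	
c8.0	-3143.1091	0.222222	-698.4687	11	1	A:36	
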