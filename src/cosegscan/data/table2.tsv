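# Thirteen co-segregating loss-of-function candidate variants in six genes,
# each recurring in two or more families. Allele frequencies below 0.001 are
# censored ("<0.001"). Genomic coordinates are NOT part of the published
# record: the loader synthesizes deterministic placeholder chrom/pos; ref and
# alt are taken from the HGVSc column.
gene	rsid	gnomad_popmax_af	topmed_af	nfe_af	consequence	sift	polyphen	phastcons7	hgvsc	hgvsp	family
DENND2C	rs189506550	<0.001	<0.001	<0.001	missense	tolerated	probably_damaging	1	c.842G>A	p.Arg281Gln	1
DENND2C	rs61753528	0.005	0.003	0.005	missense	deleterious	probably_damaging	1	c.2497T>C	p.Tyr833His	10
DNAH7	rs201273652	0.005	<0.001	<0.001	missense	deleterious	probably_damaging	1	c.3233A>T	p.Glu1078Val	8
DNAH7	rs115474479	<0.001	<0.001	<0.001	stop_gained			0.981	c.6949C>T	p.Arg2317Ter	2
NBEAL1	rs199629983	0.004	0.001	0.001	missense	deleterious	possibly_damaging	0.918	c.5252G>A	p.Arg1751His	9
NBEAL1	rs180771101	0.003	0.002	0.003	missense	deleterious	probably_damaging	1	c.987T>G	p.Phe329Leu	2
NEB	rs201548700	<0.001	<0.001	<0.001	missense	deleterious	probably_damaging	0.999	c.22187A>G	p.Lys7396Arg	4
NEB	rs114089598	0.005	0.003	0.004	missense	tolerated	probably_damaging	0.999	c.4649A>G	p.Lys1550Arg	8
NEB	rs764064217	<0.001	<0.001	<0.001	missense	tolerated	possibly_damaging	0.998	c.6011T>C	p.Val2004Ala	9
PRRC2C	rs148813704	0.004	0.003	0.004	missense	deleterious	benign	0.986	c.5980A>G	p.Asn1994Asp	3
PRRC2C	rs138220849	0.002	0.001	<0.001	missense	deleterious	benign	1	c.2191A>G	p.Met731Val	2
SHC2	rs201010410	<0.001	<0.001	<0.001	missense	deleterious	probably_damaging	0.991	c.1595T>G	p.Leu532Arg	3
SHC2	rs768095487	<0.001	<0.001	<0.001	missense	deleterious	probably_damaging	0.274	c.1510G>T	p.Asp504Tyr	4
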