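gene	hgvs	hgvs_normalized	sanger	flow_call	flow_fraction	flow_flag	alt_call	alt_fraction	alt_flag
BRCA1	c.19-47del29		het	het	56	lowdepth			lowdepth
BRCA1	c.81-12delC						het	41	
BRCA1	c.124delA		het	het	48		het	48	
BRCA1	c.212+1G>A		het	het	72	lowdepth			lowdepth
BRCA1	c.342-343delTC	c.342_343delTC	het	het	36		het	37	
BRCA1	c.671-11dup			het	45		het	43	
BRCA1	c.798-799del	c.798_799del	het	het	48		het	48	
BRCA1	c.1116G>A		het	het	43		het	43	
BRCA1	c.1390dupA		het	het	49		het	48	
BRCA1	c.1823-1826del	c.1823_1826del	het	het	46		het	46	
BRCA1	c.1953_1956delGAAA		het	het	35		het	34	
BRCA1	c.2077G>A		het	het	60		het	62	
BRCA1	c.2082C>T		hom	hom	100		hom	100	
BRCA1	c.2269delG		het	het	66		het	66	
BRCA1	c.2612C>T		het	het	42		het	42	
BRCA1	c.3113A>G		het	het	51		het	52	
BRCA1	c.3548A>G		het	het	49		het	49	
BRCA1	3839-3843del5ins4	c.3839_3843delinsAGGC	het	het	52		het	52	
BRCA1	c.4127del		het	het	56		het	44	
BRCA1	c.4214-4215delIns5						het	23	
BRCA1	c.4221delins9						het	26	
BRCA1	C.4227-4237delins16						het	24	
BRCA1	c.4243-4244delGA	c.4243_4244delGA					het	26	
BRCA1	c.4281_4282ins39		het	het	44				
BRCA1	c.4308T>C		het	het	55		het	49	
BRCA1	c.4575-4585del11		het	het	46		het	43	
BRCA1	c.4810C>T		het	het	58		het	53	
BRCA1	c.5266dupC		het	het	59		het	59	
BRCA1	c.5333-20_5333-19insT						het	25	
BRCA2	c.37_44del8		het	het	25	lowdepth	het	26	
BRCA2	c.1114A>C		het	het	47		het	51	
BRCA2	c.1246A>G		het	het	47		het	49	
BRCA2	c.1553_1554insT			het	31	lowdepth			lowdepth
BRCA2	c.1748_1749insA			het	47	lowdepth	het	26	
BRCA2	c.1759-1761delinsC						het	25	
BRCA2	c.1774delT						het	33	
BRCA2	c.1804-1806delins3						het	21	
BRCA2	c.1803dupA						het	43	
BRCA2	c.1815dupA			het	68		het	31	
BRCA2	c.1823dupA						het	33	
BRCA2	c.1833dupA						het	21	
BRCA2	c.2589T>A						het	34	
BRCA2	c.2803G>A		het	het	39		het	40	
BRCA2	c.3479G>A			het	31	lowdepth			
BRCA2	c.3807T>C		het	het	44		het	42	
BRCA2	c.4332-4333delTA	c.4332_4333delTA					het	66	
BRCA2	c.4350dupT						het	44	
BRCA2	c.4781delins3						het	22	
BRCA2	c.5073dupA		het	het	42		het	41	
BRCA2	c.5385dupA						het	22	
BRCA2	c.5459_5460insA			het	32	lowdepth			
BRCA2	c.7977-10dup						het	70	
BRCA2	c.8125dupA						het	23	
BRCA2	c.8147-8148insA						het	29	
BRCA2	c.8574dup			het	38		het	30	
BRCA2	c.8797del			hom					
BRCA2	c.8800del			het	80	lowdepth			
BRCA2	c.8823dupA						het	28	
BRCA2	c.8946dup			het	27	lowdepth			
BRCA2	c.10083del						het	21	
BRCA2	c.10115dupC						het	50	
BRCA2	c.10122delC						het	32	
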