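kind	name	start	end	parent
length	protein	1	1036
domain	PYR	1	100
domain	NACHT	131	695
subdomain	NBD	131	372	NACHT
subdomain	HD1	373	415	NACHT
subdomain	WHD	416	541	NACHT
subdomain	HD2	542	695	NACHT
domain	LRR	696	1036
motif	Walker A	226	233	NACHT
motif	Walker B	300	306	NACHT
motif	Sensor 1	348	353	NACHT
motif	GxP	410	412	NACHT
motif	Sensor 2	520	524	NACHT
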