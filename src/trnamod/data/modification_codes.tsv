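# Controlled vocabulary of modification short codes.
# affected_base uses the DNA alphabet (T stands for U); wc_face = 1 when the
# chemical group sits on the Watson-Crick edge and strongly perturbs RT.
code	chemical_name	affected_base	wc_face
m1A	1-methyladenosine	A	1
m1I	1-methylinosine	A	1
m1G	1-methylguanosine	G	1
m2G	N2-methylguanosine	G	1
m22G	N2,N2-dimethylguanosine	G	1
m22Gm	N2,N2,2'-O-trimethylguanosine	G	1
m7G	7-methylguanosine	G	0
Gm	2'-O-methylguanosine	G	0
Am	2'-O-methyladenosine	A	0
Cm	2'-O-methylcytidine	C	0
Um	2'-O-methyluridine	T	0
m5C	5-methylcytidine	C	0
ac4C	N4-acetylcytidine	C	0
t6A	N6-threonylcarbamoyladenosine	A	0
m6A	N6-methyladenosine	A	0
cnm5U	5-cyanomethyluridine	T	0
mcm5U	5-methoxycarbonylmethyluridine	T	0
Y	pseudouridine	T	0
m1Y	1-methylpseudouridine	T	1
acp3U	3-(3-amino-3-carboxypropyl)uridine	T	1
D	dihydrouridine	T	0
G+	archaeosine	G	0
imG	wyosine	G	1
xA	unresolved adenosine modification	A	0
xC	unresolved cytidine modification	C	0
xG	unresolved guanosine modification	G	0
xU	unresolved uridine modification	T	0
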