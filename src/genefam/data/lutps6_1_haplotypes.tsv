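# SNP/indel haplotypes of the linseed LuTPS6.1 gene and its 2 kb promoter in the
# CDC Bethune reference, two late flowering-maturing accessions (EC0115148,
# EC0718827) and two early flowering-maturing accessions (IC0523807, IC0525939).
# Positions are gene-relative: +1 = first base of the start codon, -1 = first
# upstream base; "-" denotes a deletion allele.
position	reference	EC0115148	EC0718827	IC0523807	IC0525939
-1903	G	G	G	A	G
-1812	C	T	C	T	T
-1529	A	A	-	A	A
-1528	C	C	-	C	C
-1484	G	G	A	G	G
-1289	A	A	-	A	A
-1288	T	T	-	T	T
-1287	A	A	-	A	A
-1286	A	A	-	A	A
-1285	A	A	-	A	A
-1284	A	A	-	A	A
-1283	A	A	-	A	A
-1253	A	G	A	G	G
-286	T	T	T	-	T
-285	C	C	C	-	C
-284	T	T	T	-	T
1143	G	A	A	G	G
1716	G	T	T	G	G
2418	T	C	C	T	T
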