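# SNP/indel haplotypes of the linseed LuTPS10.2 gene and its 2 kb promoter in
# the CDC Bethune reference, two late flowering-maturing accessions (EC0115148,
# EC0718827) and two early flowering-maturing accessions (IC0523807, IC0525939).
# Positions are gene-relative: +1 = first base of the start codon, -1 = first
# upstream base; "-" denotes a deletion allele.
position	reference	EC0115148	EC0718827	IC0523807	IC0525939
-1989	C	C	C	G	G
-1974	C	C	C	T	T
-1960	C	C	C	T	T
-1951	G	G	G	A	A
-1886	G	G	G	A	A
-1878	T	T	T	C	C
-1796	G	G	G	A	A
-1735	C	C	T	C	C
-1458	T	T	T	T	-
-1457	A	A	A	A	-
-1456	A	A	A	A	-
-1455	A	A	A	A	-
-1117	-	-	-	C	C
-1116	-	-	-	T	T
-984	C	C	C	T	C
-685	T	T	T	-	-
-627	-	-	-	C	C
-626	-	-	-	A	A
-625	-	-	-	A	A
-624	-	-	-	T	T
-623	-	-	-	G	G
-622	-	-	-	T	T
-621	-	-	-	G	G
-620	-	-	-	A	A
-619	-	-	-	G	G
-618	-	-	-	T	T
-617	-	-	-	T	T
1063	C	C	C	T	T
2439	G	G	G	T	T
2624	A	A	A	G	G
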