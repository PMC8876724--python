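position	alt	source
11386	C	li2012
12285	C	li2012
12684	A	li2012
12705	T	li2012
13095	C	li2012
13105	G	li2012
16519	C	li2012
16527	T	li2012
13062	G	initial_review
16129	A	initial_review
16390	A	initial_review
16399	G	initial_review
16444	T	initial_review
16496	A	initial_review
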