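# sent_id = example-target
# interpretation = passive
1	The	_	_	_	_	2	det	_	_
2	dog	_	_	_	_	8	nsubj:pass	_	_
3	found	_	_	_	_	2	acl	_	_
4	in	_	_	_	_	3	prep	_	_
5	the	_	_	_	_	6	det	_	_
6	park	_	_	_	_	4	pobj	_	_
7	was	_	_	_	_	8	aux	_	_
8	covered	_	_	_	_	0	root	_	_
9	in	_	_	_	_	8	prep	_	_
10	mud	_	_	_	_	9	pobj	_	_

# sent_id = example-target
# interpretation = active
1	The	_	_	_	_	2	det	_	_
2	dog	_	_	_	_	3	nsubj	_	_
3	found	_	_	_	_	0	root	_	_
4	in	_	_	_	_	3	prep	_	_
5	the	_	_	_	_	6	det	_	_
6	park	_	_	_	_	4	pobj	_	_
7	was	_	_	_	_	8	aux	_	_
8	covered	_	_	_	_	3	dep	_	_
9	in	_	_	_	_	8	prep	_	_
10	mud	_	_	_	_	9	pobj	_	_
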