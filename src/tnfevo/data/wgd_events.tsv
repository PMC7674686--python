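# Whole-genome duplication events, keyed by the child node of the branch that
# carries them. Events on a branch are ordered oldest first. The root node's
# name addresses the stem lineage above the root.
branch	events
vertebrate_ancestor	WGD1,WGD2
teleost_ancestor	TS_WGD
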