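# Restriction enzyme -> recognition motif (forward strand; all palindromic)
# Extend by passing --enzyme-table with the same two-column format.
HindIII	AAGCTT
NcoI	CCATGG
Sau3AI	GATC
MluCI	AATT
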