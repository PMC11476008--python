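# Default reference regions and residue sets on human PRPS1 numbering.
# Editable defaults: region windows approximate the flexible-loop elements of
# the PRPS1 homodimer structure; only the catalytic residue set is fixed by
# well-established enzymology (D171 metal, K194 ATP, R196/T225 R5P, N200
# catalytic-loop stabilisation).  Interface and allosteric set membership is
# analysis-specific and must be supplied by the user (uncomment and edit the
# template lines below).
name	kind	value
FLAG	region	31-45
regulatory_loop	region	92-108
CF_loop	region	128-144
PP_loop	region	170-174
R5P_loop	region	213-228
catalytic	set	D171,K194,R196,N200,T225
# bent_dimer	set	<user-supplied, e.g. R49,E52,...>
# parallel_dimer	set	<user-supplied>
# allosteric_I	set	<user-supplied>
# allosteric_II	set	<user-supplied>
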