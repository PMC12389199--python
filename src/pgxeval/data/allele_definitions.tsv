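# Star-allele function assignments following CPIC allele-function tables.
# CYP2D6 activity_value is the per-copy activity-score contribution;
# CYP2C19 translation is function-class based, so activity_value is blank.
# Uncertain-function alleles have no activity value and translate to
# Indeterminate phenotypes.
gene	allele	function_class	activity_value
CYP2C19	*1	normal
CYP2C19	*2	no_function
CYP2C19	*3	no_function
CYP2C19	*4	no_function
CYP2C19	*5	no_function
CYP2C19	*6	no_function
CYP2C19	*8	no_function
CYP2C19	*9	decreased
CYP2C19	*10	decreased
CYP2C19	*17	increased
CYP2C19	*12	uncertain
CYP2D6	*1	normal	1.0
CYP2D6	*2	normal	1.0
CYP2D6	*3	no_function	0
CYP2D6	*4	no_function	0
CYP2D6	*5	no_function	0
CYP2D6	*6	no_function	0
CYP2D6	*7	no_function	0
CYP2D6	*8	no_function	0
CYP2D6	*9	decreased	0.25
CYP2D6	*10	decreased	0.25
CYP2D6	*17	decreased	0.5
CYP2D6	*29	decreased	0.5
CYP2D6	*36	no_function	0
CYP2D6	*41	decreased	0.25
CYP2D6	*36+*10	decreased	0.25
CYP2D6	*22	uncertain
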