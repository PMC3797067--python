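# mitorho packaged mini haplogroup tree (rCRS-relative diagnostics).
#
# Diagnostics of the named terminal subclades follow published control- and
# coding-region motifs (e.g. M5a1b: G1303A-A6461G; M5a1b1: C3954T;
# M5a1b1a: T9833C; M5a1b1a1: T16298C; M18: T246C, A16318T; the M35b2a1
# profile G16129A-C16223T-A16230G-C16233T-T16304C-C16344T; U3: A16343G;
# U3b1c: A2833G-T7759C-T8895C-C11119T-T12783C-T15262C; H5a2:
# T152C-C16186T plus C11047T; H24: A16293G; H88a: T3621C-A12712G;
# L2c: A93G-C198T-C325T-C16320T).
#
# Scaffolding nodes for which no motif is published here (M1, M35 stem,
# U3b/U3b1, HV/H/H5a/H88 stems, L internals, A2) carry SCHEMATIC stand-in
# diagnostics chosen for testability. This file is a classification aid,
# not a nomenclature authority.
#
#version: mitorho-mini-1
#alias A16344G=A16343G
ROOT
	L	A73G A263G C16223T
		L1b	T16126C C16187T T16189C G16213A C16270T A16293G
		L2	C16278T G16390A
			L2c	A93G C198T C325T C16320T
	M	C16223T C10400T
		M1	G6446A T6680C T16249C
			M1a1	C16185T T16311C
		M5	G16129A
			M5a	C16291T A10754G
				M5a1	T146C
					M5a1a	G185A T334C G9064A G11016A
					M5a1b	G1303A A6461G
						M5a1b1	C3954T
							M5a1b1a	T9833C
								M5a1b1a1	T16298C
		M18	T246C A16318T
		M35	A5153G
			M35b	T16304C
				M35b2	T5426C
					M35b2a	A16230G C16233T
						M35b2a1	G16129A C16344T
	N	A73G A263G
		A2	C16111T C16223T C16290T G16319A T16362C
		U	A12308G
			U3	A16343G
				U3b	C6045T
					U3b1	A9006G
						U3b1c	A2833G T7759C T8895C C11119T T12783C T15262C
		HV	G6152A
			H	T7645C
				H5	T16304C
					H5a	G5471A
						H5a2	T152C C16186T C11047T
				H24	A16293G
				H88	A5301G
					H88a	T3621C A12712G
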