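protein	pdb_id	chain_length	position	res_name	method	validated
gene V	1YHA	87	35	VAL	both	1
gene V	1YHA	87	45	VAL	both	1
gene V	1YHA	87	47	ILE	structure	1
gene V	1YHA	87	63	VAL	structure	1
gene V	1YHA	87	81	LEU	structure	1
gene V	1YHA	87	78	ILE	sequence	1
lambda repressor	1LMB	92	51	PHE	both	1
lambda repressor	1LMB	92	65	LEU	both	1
lambda repressor	1LMB	92	76	PHE	both	1
lambda repressor	1LMB	92	84	ILE	both	1
lambda repressor	1LMB	92	18	LEU	structure	1
lambda repressor	1LMB	92	36	VAL	structure	1
lambda repressor	1LMB	92	47	VAL	structure	1
T4 lysozyme	2LZM	164	6	MET	both	1
T4 lysozyme	2LZM	164	102	MET	both	1
T4 lysozyme	2LZM	164	149	VAL	structure	1
T4 lysozyme	2LZM	164	153	PHE	structure	1
T4 lysozyme	2LZM	164	103	VAL	sequence	1
CcdB	3VUB	101	17	PHE	both	1
CcdB	3VUB	101	18	VAL	both	1
CcdB	3VUB	101	33	VAL	both	1
CcdB	3VUB	101	34	ILE	both	1
CcdB	3VUB	101	54	VAL	both	1
CcdB	3VUB	101	5	VAL	structure	1
CcdB	3VUB	101	36	LEU	structure	1
CcdB	3VUB	101	63	MET	structure	1
CcdB	3VUB	101	50	LEU	sequence	1
CcdB	3VUB	101	53	VAL	sequence	0
CcdB	3VUB	101	96	LEU	sequence	1
CcdB	3VUB	101	97	MET	sequence	1
CcdB	3VUB	101	98	PHE	sequence	1
Gal4	3COQ	88	68	PHE	both	1
Gal4	3COQ	88	69	LEU	sequence	1
Gal4	3COQ	88	70	LEU	sequence	1
Ura3	1DQW	267	25	MET	structure	1
Ura3	1DQW	267	32	LEU	structure	1
Ura3	1DQW	267	118	ILE	structure	1
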