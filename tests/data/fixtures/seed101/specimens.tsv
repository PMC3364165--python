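specimen_id	family	genus	species	id_confidence	life_stage	country	state_province	latitude	longitude
SIM0001	Family01	Genusa	Genusa species01	expert	subimago	Canada	SK	58.589	-83.693
SIM0002	Family01	Genusa	Genusa species01	expert	imago	United States	CO	27.765	-93.499
SIM0003	Family01	Genusa	Genusa species01	expert	imago	Canada	MT	49.205	-84.84
SIM0004	Family01	Genusa	Genusa species02	expert	imago	Canada	SK	59.363	-123.05
SIM0005	Family01	Genusa	Genusa species02	expert	subimago	United States	NY	34.067	-79.521
SIM0006	Family01	Genusa	Genusa species02	expert	imago	United States	AB	46.836	-121.733
SIM0007	Family01	Genusb	Genusb species02	expert	subimago	Canada	MT	50.201	-121.499
SIM0008	Family01	Genusb	Genusb species01	expert	subimago	United States	MB	45.006	-91.493
SIM0009	Family01	Genusb	Genusb species01	expert	subimago	United States	BC	38.293	-87.107
SIM0010	Family01	Genusb	Genusb species02	expert	subimago	United States	MB	38.114	-127.851
SIM0011	Family01	Genusb	Genusb species02	expert	imago	United States	ON	44.28	-92.317
SIM0012	Family01	Genusb	Genusb species02	expert	larva	Canada	QC	52.667	-125.442
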