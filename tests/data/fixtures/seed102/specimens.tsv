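specimen_id	family	genus	species	id_confidence	life_stage	country	state_province	latitude	longitude
SIM0001	Family01	Genusa	Genusa species01	expert	larva	United States	NB	28.08	-100.207
SIM0002	Family01	Genusa	Genusa species01	expert	subimago	United States	QC	34.449	-114.397
SIM0003	Family01	Genusa	Genusa species01	expert	larva	United States	OR	39.747	-65.883
SIM0004	Family01	Genusa	Genusa species01	expert	imago	United States	OR	43.581	-98.346
SIM0005	Family01	Genusa	Genusa species02	expert	imago	United States	OR	40.682	-63.492
SIM0006	Family01	Genusa	Genusa species02	expert	subimago	United States	OR	39.151	-113.231
SIM0007	Family01	Genusb	Genusb species01	expert	subimago	United States	NY	34.332	-126.408
SIM0008	Family01	Genusb	Genusb species01	expert	imago	Canada	BC	57.942	-92.389
SIM0009	Family01	Genusb	Genusb species01	expert	subimago	United States	NB	39.023	-84.852
SIM0010	Family01	Genusb	Genusb species02	expert	subimago	United States	BC	27.106	-84.638
SIM0011	Family01	Genusb	Genusb species02	expert	imago	United States	CO	28.794	-81.909
SIM0012	Family01	Genusb	Genusb species02	expert	subimago	United States	ON	35.223	-69.756
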