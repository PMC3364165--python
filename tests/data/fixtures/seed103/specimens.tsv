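specimen_id	family	genus	species	id_confidence	life_stage	country	state_province	latitude	longitude
SIM0001	Family01	Genusa	Genusa species01	expert	subimago	Canada	NY	51.557	-121.415
SIM0002	Family01	Genusa	Genusa species01	expert	larva	United States	AB	36.11	-85.943
SIM0003	Family01	Genusa	Genusa species01	expert	subimago	Canada	AB	59.722	-61.904
SIM0004	Family01	Genusa	Genusa species02	expert	subimago	United States	SK	28.683	-105.627
SIM0005	Family01	Genusa	Genusa species01	expert	subimago	Canada	BC	50.529	-75.462
SIM0006	Family01	Genusa	Genusa species02	expert	subimago	United States	QC	30.058	-128.712
SIM0007	Family01	Genusb	Genusb species01	expert	subimago	United States	AB	39.001	-77.07
SIM0008	Family01	Genusb	Genusb species01	expert	subimago	United States	NY	42.898	-88.169
SIM0009	Family01	Genusb	Genusb species01	expert	imago	United States	MT	29.327	-71.199
SIM0010	Family01	Genusb	Genusb species02	expert	larva	United States	AB	48.518	-122.041
SIM0011	Family01	Genusb	Genusb species02	expert	subimago	United States	QC	35.643	-92.538
SIM0012	Family01	Genusb	Genusb species02	expert	imago	United States	BC	32.865	-98.261
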