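specimen_id	true_species	assigned_species	cluster	is_misidentified	is_fragment	has_ambiguity
SIM0001	Genusa species01	Genusa species01	0	False	True	True
SIM0002	Genusa species01	Genusa species01	0	False	False	True
SIM0003	Genusa species01	Genusa species01	0	False	False	False
SIM0004	Genusa species02	Genusa species01	0	True	False	True
SIM0005	Genusa species02	Genusa species02	1	False	False	False
SIM0006	Genusa species02	Genusa species02	0	False	False	True
SIM0007	Genusb species01	Genusb species01	0	False	False	True
SIM0008	Genusb species01	Genusb species01	0	False	False	True
SIM0009	Genusb species01	Genusb species01	0	False	False	True
SIM0010	Genusb species02	Genusb species02	0	False	True	False
SIM0011	Genusb species02	Genusb species02	0	False	False	True
SIM0012	Genusb species02	Genusb species02	0	False	False	True
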