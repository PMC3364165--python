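{
  "seed": 102,
  "n_genera": 2,
  "species_per_genus": 2,
  "specimens_per_species": 3,
  "seq_length": 658,
  "kappa": 3.0,
  "intra_depth": 0.02,
  "inter_depth": 0.12,
  "between_genus_depth": 0.25,
  "genera_per_family": 2,
  "cryptic_fraction": 0.25,
  "split_depth": 0.08,
  "fragment_fraction": 0.2,
  "fragment_length": 325,
  "ambiguity_rate": 0.002,
  "misid_count": 1,
  "provisional_fraction": 0.2
}
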