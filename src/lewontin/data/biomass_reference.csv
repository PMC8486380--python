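phylum,total_species,biomass_gtc,sample_biomass_gtc,n_species
Arthropoda,1.26e6,1.20,2.80e-4,68
Chordata,5.41e4,0.87,2.67e-2,68
Annelida,1.70e4,0.20,1.23e-5,3
Mollusca,9.54e4,0.20,4.56e-4,13
Cnidaria,1.60e4,0.10,3.07e-5,2
Nematoda,2.50e4,0.02,4.03e-6,1
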