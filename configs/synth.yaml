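# Synthetic fixtures: an indicator table with the default Red List
# composition plus LPI/GBF records, and a geo-referenced genotype panel.
species_table:
  n_lpi: 500
  n_gbf: 200
panel:
  n_individuals: 200
  n_loci: 1000
  fst: 0.2
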