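# Default synthetic study scenario: 90 counties in the nine Farm Resource
# Regions, 1997-2012, census years 1997/2002/2007/2012.  Omitted keys
# (including the compound catalog) take the package defaults; pass --seed on
# the command line to override the seed here.
n_counties: 90
years: [1997, 2012]
census_years: [1997, 2002, 2007, 2012]
p_missing_use: 0.05      # probability a county-year is absent from use data
p_withheld: 0.10         # probability a census cell is withheld
high_multiplier: 1.5     # kg_high = 1.5 x kg_low
n_urban: 2               # counties with no agricultural insecticide use
n_ca_like: 3             # Fruitful Rim counties lacking seed-treatment data
target_oral_fold: 9.0    # planted national oral toxic-load fold change
target_contact_fold: 1.0
seed: 0
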