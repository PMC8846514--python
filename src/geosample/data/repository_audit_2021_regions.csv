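# Published 2021 census of public human-microbiome samples in the INSDC
# repositories (SRA / ENA / DDBJ via NCBI BioSample), aggregated to the eight
# UN SDG regions and, separately, to the UN least-developed-countries (LDC)
# grouping, with UN 2020 population estimates in thousands. "block" separates
# the two groupings; rows without a population (Unknown) have no resolved
# location and are excluded from known-location denominators.
block,unit,samples,population_thousands
sdg_region,Europe and Northern America,272544,1116506
sdg_region,Eastern and Southeastern Asia,49007,2346709
sdg_region,Sub-Saharan Africa,18651,1094366
sdg_region,Latin America and the Caribbean,15264,653962
sdg_region,Australia/New Zealand,13620,30322
sdg_region,Central and Southern Asia,6685,2014709
sdg_region,Northern Africa and Western Asia,5621,525869
sdg_region,Oceania,1178,12356
sdg_region,Unknown,62259,
ldc,Least developed countries,15254,1057438
ldc,Rest of world,367457,6737361
ldc,Unknown,62118,
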