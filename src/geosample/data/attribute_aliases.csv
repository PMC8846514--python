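alias,canonical
geographic location,geo_loc_name
geographic location (country and/or sea),geo_loc_name
geographic location (country and/or sea region),geo_loc_name
geo loc name,geo_loc_name
country,geo_loc_name
host taxid,host_taxid
host_taxon_id,host_taxid
host taxonomy id,host_taxid
host organism,host
host species,host
host common name,host
specific_host,host
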