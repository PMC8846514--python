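# Body-site taxonomy-ID table: maps NCBI metagenome taxonomy categories to the
# 19 audited body-site labels. "human_taxid" is the category explicitly labeled
# human (e.g. "human gut metagenome", txid 408170); "generic_taxid" is the
# host-agnostic sibling category (e.g. "gut metagenome") whose samples are only
# admitted when a host attribute indicates a human. The "human metagenome"
# category names no body site and has no generic sibling. Anchor IDs (408170,
# 646099, 749906) follow the NCBI Taxonomy; verify the remaining IDs against a
# current NCBI Taxonomy export before any live harvest — this packaged copy is
# editable configuration primarily exercised by synthetic cohorts.
body_site,human_taxid,generic_taxid
gut,408170,749906
human metagenome,646099,
oral,447426,1764537
skin,539655,1011528
vaginal,1632839,1549806
lung,433733,1384484
nasopharyngeal,1131769,2593991
feces,1115769,1861841
reproductive system,1842734,2754716
blood,1504969,655179
saliva,1679718,1510571
milk,1633571,1920934
urinary tract,1852385,2708305
tracheal,2703656,2814868
sputum,2593396,2135620
eye,1774969,2708350
semen,2711145,2795351
bile,2726069,2777915
skeleton,2724709,2775858
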