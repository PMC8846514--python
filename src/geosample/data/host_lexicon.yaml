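# Host lexicon: decides whether a free-text "host" / "host_taxid" value from a
# generic metagenome category indicates a human host. Positive tokens are
# matched case-insensitively as substrings; negative overrides veto a positive
# match when another species is named (matched on word boundaries). Replaces
# manual curation with an auditable, overridable rule set.
human_taxids: [9606]
positive_tokens:
  - human
  - homo sapiens
  - homo sapien
  - patient
  - crew member
  - crewmember
  - infant
  - adult
  - child
  - volunteer
  - subject
negative_overrides:
  - mus musculus
  - mouse
  - mice
  - murine
  - rat
  - rattus
  - canine
  - dog
  - canis
  - feline
  - felis
  - cat
  - pig
  - piglet
  - sus scrofa
  - porcine
  - swine
  - bovine
  - cow
  - calf
  - cattle
  - bos taurus
  - chicken
  - gallus
  - macaque
  - macaca
  - chimpanzee
  - pan troglodytes
  - gorilla
  - rhesus
  - ovine
  - sheep
  - ovis
  - goat
  - capra
  - horse
  - equine
  - equus
  - rabbit
  - oryctolagus
  - zebrafish
  - danio
  - simulated
  - gnotobiotic
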