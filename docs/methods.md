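# Methods

## Problem and model

The package audits where publicly deposited human-microbiome samples come
from. The unit of analysis is the BioSample metadata record, not the
sequencing run and not the human subject: repeated sampling of one subject
counts once per deposited sample. Representation of a unit (country, UN SDG
region, or country group) is measured against population share:

    repr_proportion(u) = (samples_u / samples_located) / (pop_u / pop_world)

with 1 meaning proportional representation. The signed index used for
mapping keeps the ratio on the overrepresented side and takes the negative
reciprocal on the underrepresented side, so its magnitude is always "how
many times off proportionality" and its sign is the direction. Exact
proportionality is assigned to the positive branch with value 1 (the
definition only fixes the strict cases; a tie must land somewhere, and 1 is
the natural anchor shared by both formulas at equality).

## Scoping rules

A record enters the audited cohort if either

- its taxonomy category is explicitly human ("human gut metagenome" …,
  mapped to 19 body-site labels by the packaged body-site table; the "human
  metagenome" category names no body site and is carried as its own label), or
- its category is the host-agnostic generic sibling ("gut metagenome" …),
  the category holds at least 1,000 samples (inclusive), and its putative
  host value — `host_taxid`, falling back to `host` when `host_taxid` is
  blank or a null token — indicates a human.

Host flagging replaces one-off manual curation with a lexicon: a value is
human if it parses to a human taxid (default {9606}), or contains a positive
token ("human", "homo sapiens", "patient", "crew member", "infant", "adult",
"child", "volunteer", "subject") and no word-boundary match of a negative
override (other species names: "mouse", "sus scrofa", …). Substring matching
for positives keeps "humans"/"Human adult" positive; word-boundary matching
for negatives avoids accidental vetoes from substrings while still rejecting
"adult Sus scrofa" or "humanized mouse". Every distinct host value's
decision is retained in the scoping report for audit.

## Geographic attribution

The first present attribute among `geo_loc_name`, "geographic location
(country and/or sea)", "geographic location" is split on the first colon
(INSDC "Country: subdivision" convention). Null tokens ("missing", "not
collected", "not applicable", "restricted access", "unknown", empty) mean no
geography. The country token is looked up case- and diacritic-insensitively
in a gazetteer built from canonical UN names, ISO-3166 alpha-3 codes and a
shipped synonym table; unmatched tokens are counted as Unknown rather than
guessed, and ambiguous historical names ("Korea") are deliberately absent
from the gazetteer. Sub-national UN units such as Hong Kong and Puerto Rico
are kept as their own entries. Antarctica resolves to a country code (so
country-level tables can report it) but belongs to no SDG region, so
region-level tables pool it into Unknown — which is why the Unknown total
can differ slightly between country-level and region-level tables of the
same cohort.

The packaged world table carries 192 countries/territories with UN 2020
population estimates (thousands), the 8 SDG regions, and the 47-member LDC
list. It covers every country named in the published census and all LDCs;
the remaining UN microstates are omitted as they have never contributed
samples at a scale that affects the statistics, and the table is editable
configuration for anyone who needs the full list.

## Index scaling and display

Units with 50 or fewer samples ("50 or fewer" — inclusive) are excluded
before scaling; units with zero samples keep a distinct no-samples sentinel.
Positive scores scale by x → 100·x/max(x), negative by x → −100·|x|/max|x|:
the simplest maps onto (0, 100] / [−100, 0) that preserve sign, within-sign
order and the 0 anchor. The display transform is sign(x)·log10(1+|x|); the
+1 offset keeps 0 finite and the map monotone. Any monotone sign-preserving
variant would serve the same purpose (color variation), so the exact form is
a documented package choice.

Printed-style output rounds half-away-from-zero at the stated precision;
all internal arithmetic is full precision.

## Synthetic cohorts

The generator emulates the metadata structure of a repository dump:
multinomial country composition (default: proportional to the published
top-20 per-country counts of the 2021 census), body-site mixture over the 19
categories (default: proportional to the published per-site counts), 29%
generic-category records with a 17.3% human-host rate, 14% missing
geography (half null tokens, half absent attributes), 30% messy spellings
(synonyms, "Country: subdivision" forms), 0.2% records with no linked runs,
release years 2010–2020 following the repository's observed growth curve,
and a 72% AMPLICON share among runs. One seeded NumPy generator drives all
draws in a fixed field order, so a fixed seed gives byte-identical output.
Ground truth records every per-record draw, so stage-by-stage pipeline
counts can be checked exactly.

What the generator does **not** emulate: real attribute vocabulary breadth
(thousands of distinct tags and 4,000+ distinct host strings), misfiled
samples (human microbiome data deposited under "Homo sapiens"),
non-ISO-parseable dates, and correlation between geography and body site or
year. Passing tests therefore demonstrate that the pipeline's rules are
implemented correctly and calibrated (representation proportions → 1 under
population-proportional sampling), not that the lexicon or gazetteer would
capture every real-world spelling.

## Problem sizes and test design

Unit and property tests run on cohorts of 300–2,000 records; distributional
recovery is checked at n = 10,000 (3σ binomial bands per country) and
calibration at n = 50,000 under population-proportional country weights,
using exact central 99.7% binomial intervals — equivalent to 3σ in the CLT
regime and correct for the many countries whose expected count at this n is
small. Tabulation is verified against brute-force counting oracles and the
generator's ground truth; the published 2021 census tables (per-region
counts with populations) are pushed through the same arithmetic as pipeline
output to confirm the printed proportions.

Two printed proportions do not reproduce from their own table's counts:
Australia/New Zealand recomputes to 9.15 (printed 9.14) and Latin America
and the Caribbean to 0.48 (printed 0.49), a ±0.01 discrepancy presumably
from unprinted denominator details; they are documented here and not
asserted. The published 72.0% AMPLICON share likewise has an ambiguous
denominator, so the pipeline reports its own amplicon run share without
pinning that value.

## Limitations

- The lexicon and gazetteer are behavior-class replicas of a manual curation
  effort, not string-for-string reproductions; live-harvest results will
  differ in the tail of rare spellings.
- Full-scale census numbers (≈445k samples, 115 origin countries) require a
  live NCBI harvest; the eUtils client provides the interface but the
  package makes no network calls in tests.
- Body-site taxonomy IDs other than the anchored ones are placeholders to be
  checked against a current NCBI Taxonomy export before production use.
- Country-level statistics inherit every bias of depositor-supplied
  metadata, including sequencing-center-instead-of-origin errors.
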